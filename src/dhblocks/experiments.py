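"""Seeded recovery experiments: the package's self-validation battery.

Each function simulates populations with known ground truth, runs the
inference path under test, and measures agreement against an independent
oracle (exhaustive path enumeration, or a region scan over the true origin
labels). They power both the test suite and ``scripts/acceptance.py``.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import coseg, hmm, metabolites as met
from . import simulate as sim
from ._util import MISSING, P1, P2


def brute_force_best_logprob(calls, positions, params: hmm.HmmParams) -> float:
    """Max joint log-probability over all 3^n state paths, by enumeration."""
    n = len(calls)
    obs = np.array([{P1: 0, P2: 1, "HET": 2, MISSING: 3}[str(c)] for c in calls])
    paths = np.array(list(itertools.product(range(3), repeat=n)), dtype=np.intp)
    log_e = hmm.emission_log_matrix(params)
    with np.errstate(divide="ignore"):
        lp = np.log(hmm.stationary_distribution(params))[paths[:, 0]]
    lp = lp + log_e[paths[:, 0], obs[0]]
    for t in range(1, n):
        with np.errstate(divide="ignore"):
            log_t = np.log(hmm.transition_matrix(float(positions[t] - positions[t - 1]), params))
        lp += log_t[paths[:, t - 1], paths[:, t]] + log_e[paths[:, t], obs[t]]
    return float(lp.max())


def viterbi_optimality(seed: int, n_sequences: int = 200, n_markers: int = 10) -> dict:
    """Fraction of random short sequences where Viterbi attains the brute-force max."""
    rng = np.random.default_rng(seed)
    params = hmm.HmmParams()
    optimal = 0
    for _ in range(n_sequences):
        calls = rng.choice([P1, P2, "HET", MISSING], size=n_markers, p=[0.4, 0.4, 0.1, 0.1])
        positions = np.cumsum(rng.integers(1_000, 100_000, size=n_markers))
        path = hmm.viterbi_path(calls, positions, params)
        lp = hmm.path_joint_logprob(path, calls, positions, params)
        best = brute_force_best_logprob(calls, positions, params)
        optimal += bool(np.isclose(lp, best, rtol=1e-10, atol=1e-9))
    return {"fraction_optimal": optimal / n_sequences, "n": n_sequences}


def _population_config(seed: int, n_lines: int, lam: float, eps: float,
                       missing: float = 0.01,
                       causal: sim.CausalRegion | None = None) -> sim.SimulationConfig:
    return sim.SimulationConfig(
        chrom_lengths={"A03": 10_000_000},
        marker_density=1e-4,
        n_dh_lines=n_lines,
        crossover_rate_lambda=lam,
        genotype_error_eps=eps,
        missing_rate=missing,
        causal_region=causal or sim.CausalRegion("A03", 3_000_000, 6_000_000, P1),
        seed=seed,
    )


def block_recovery(seed: int, n_lines: int = 50, lam: float = 2.0,
                   eps: float = 0.02) -> dict:
    """Per-marker label recovery of the HMM on one simulated population."""
    cfg = _population_config(seed, n_lines, lam, eps)
    res = sim.simulate_population(cfg)
    pos = [m.position for m in res.markers]
    params = hmm.HmmParams()
    correct = total = 0
    for line in res.truth.lines:
        raw = res.calls[line]["A03"]
        path = hmm.viterbi_path(raw, pos, params)
        truth_labels = res.truth.labels_at_markers(line, res.markers, "A03")
        nonmiss = raw != MISSING
        correct += int((path[nonmiss] == truth_labels[nonmiss]).sum())
        total += int(nonmiss.sum())
    return {"recovery": correct / total, "n": total}


def noiseless_exactness(seed: int, n_lines: int = 50, lam: float = 2.0) -> dict:
    """With eps = 0: recovery must be exact and every inferred breakpoint
    interval must contain a true crossover."""
    cfg = _population_config(seed, n_lines, lam, eps=0.0, missing=0.0)
    res = sim.simulate_population(cfg)
    pos = [m.position for m in res.markers]
    # error-free data: a vanishing emission error keeps even single-marker
    # true segments (absorbing one would cost far more than two switches),
    # and merging is disabled so blocks mirror truth segments exactly
    params = hmm.HmmParams(eps=1e-12, min_block_markers=1)
    mislabeled = 0
    breakpoints = breakpoints_ok = 0
    total = 0
    for line in res.truth.lines:
        raw = res.calls[line]["A03"]
        path = hmm.viterbi_path(raw, pos, params)
        truth_labels = res.truth.labels_at_markers(line, res.markers, "A03")
        mislabeled += int((path != truth_labels).sum())
        total += len(path)
        blocks = hmm.path_to_blocks(path, pos, params, raw_calls=raw,
                                    line=line, chromosome="A03")
        xos = res.truth.crossovers[line]["A03"]
        for a, b in zip(blocks, blocks[1:]):
            breakpoints += 1
            breakpoints_ok += any(a.end < x < b.start for x in xos)
    return {
        "mislabeled": mislabeled,
        "n": total,
        "breakpoints": breakpoints,
        "breakpoints_localised": breakpoints_ok,
    }


@dataclass
class RegionRecoveryResult:
    n_sims: int
    exact: int  # called regions over the causal interval equal the truth-scan oracle
    detected: int  # a single called region covers every marker of the planted locus
    permutation_clean: int  # random groups yield no surviving region


def region_recovery(seed: int, n_sims: int = 100, n_lines: int = 20,
                    lam: float = 0.35, min_markers: int = 10) -> RegionRecoveryResult:
    """Planted-locus recovery under map-consistent recombination.

    The simulated crossover rate matches the decoder's genetic-map density
    (lambda = rho * L = 0.35 expected crossovers over 10 Mb at 3.5 cM/Mb).
    The oracle is the same region scan run on the *true* origin labels.
    """
    causal = sim.CausalRegion("A03", 4_450_000, 4_550_000, P1)
    base = np.random.SeedSequence(seed)
    sim_seeds = base.generate_state(n_sims) % (2**31)
    exact = detected = perm_clean = done = 0
    for s in sim_seeds:
        cfg = _population_config(int(s), n_lines, lam, eps=0.02, causal=causal)
        res = sim.simulate_population(cfg)
        high = [l for l in res.truth.lines if res.truth.groups[l] == "high"]
        low = [l for l in res.truth.lines if res.truth.groups[l] == "low"]
        if not high or not low:
            continue
        done += 1
        pos = [m.position for m in res.markers]
        oracle = coseg.find_cosegregating_regions(
            res.markers, sim.truth_to_blocks(res.truth, res.markers),
            high, low, min_markers=min_markers)
        called_blocks = {
            l: hmm.call_blocks({"A03": (pos, res.calls[l]["A03"])}, line=l)
            for l in res.truth.lines
        }
        called = coseg.find_cosegregating_regions(
            res.markers, called_blocks, high, low, min_markers=min_markers)

        def over_causal(regions):
            return [(r.start, r.end) for r in regions
                    if r.start <= causal.end and r.end >= causal.start]

        o, c = over_causal(oracle), over_causal(called)
        exact += o == c
        detected += len(c) == 1 and c[0][0] <= causal.start and c[0][1] >= causal.end
        # control: groups permuted independently of genotype
        rng = np.random.default_rng(int(s) + 1)
        lines = list(res.truth.lines)
        rng.shuffle(lines)
        half = len(lines) // 2
        perm = coseg.find_cosegregating_regions(
            res.markers, called_blocks, lines[:half], lines[half:], min_markers=min_markers)
        perm_clean += not perm
    return RegionRecoveryResult(done, exact, detected, perm_clean)


def letter_separation(seed: int, n_sims: int = 100, shift: float = 10.0) -> dict:
    """A level shifted by `shift` sd must never share a post-hoc letter with nulls."""
    base = np.random.SeedSequence(seed)
    separated = 0
    for s in base.generate_state(n_sims) % (2**31):
        rng = np.random.default_rng(int(s))
        groups = {
            "null_1": rng.normal(0.0, 1.0, 10),
            "null_2": rng.normal(0.0, 1.0, 10),
            "shifted": rng.normal(shift, 1.0, 10),
        }
        comp = met.anova_with_letters(groups)
        shared = set(comp.letters["shifted"]) & (
            set(comp.letters["null_1"]) | set(comp.letters["null_2"])
        )
        separated += not shared
    return {"separated": separated, "n": n_sims}
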
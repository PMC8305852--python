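"""Recombinant-block segmentation of per-marker origin calls.

Each DH line's chromosome is a mosaic of segments inherited intact from one
parent. Raw per-marker origin calls carry genotyping error, so segmentation
uses a 3-state hidden Markov model over {P1, P2, HET}:

* emissions: the observed call matches the hidden state with probability
  1 - eps, is each wrong label with probability eps/2, and MISSING is emitted
  with probability 1 by every state (missing markers carry no evidence but
  their positions still count toward transition distances);
* transitions between adjacent markers use the Haldane map function
  r = (1 - exp(-2d))/2 with d = distance_bp * rho * 1e-8 Morgans, so the
  P1<->P2 switch probability is exactly r, and the HET state is entered with
  probability proportional to its stationary weight ``het_prior``.

The maximum-a-posteriori state path (Viterbi) is then cut into maximal
constant-label runs; runs supported by fewer than ``min_block_markers``
markers are merged into their better-supported flank, which absorbs isolated
genotyping errors without any window-size tuning. Block coordinates are
marker-bounded: first and last supporting marker position, 1-based inclusive.

A windowed majority-vote mode is provided for cross-checking only.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._util import HET, MISSING, P1, P2, ConfigError

logger = logging.getLogger(__name__)

_STATES = (P1, P2, HET)
_STATE_INDEX = {s: i for i, s in enumerate(_STATES)}
_OBS_INDEX = {P1: 0, P2: 1, HET: 2, MISSING: 3}


@dataclass
class HmmParams:
    """Tunable parameters of the block-calling HMM.

    eps
        Emission error probability: chance a marker call disagrees with the
        underlying origin.
    rho
        Recombination rate in cM/Mb. The default 3.5 approximates a ~1000 cM
        genetic map over a ~283 Mb *B. rapa* genome.
    het_prior
        Stationary weight of the HET state; ideal DH lines are homozygous so
        this is kept small but non-zero.
    min_block_markers
        Blocks supported by fewer markers are merged into a flank.
    """

    eps: float = 0.02
    rho: float = 3.5
    het_prior: float = 0.01
    min_block_markers: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.eps < 0.5:
            raise ConfigError(f"eps={self.eps} outside (0, 0.5)")
        if self.rho <= 0:
            raise ConfigError("rho must be > 0")
        if not 0.0 <= self.het_prior < 1.0:
            raise ConfigError(f"het_prior={self.het_prior} outside [0, 1)")
        if self.min_block_markers < 1:
            raise ConfigError("min_block_markers must be >= 1")


@dataclass(frozen=True)
class Block:
    """Maximal run of one parental origin in one line, marker-bounded."""

    line: str
    chromosome: str
    start: int  # bp of first supporting marker, 1-based
    end: int  # bp of last supporting marker, 1-based inclusive
    label: str
    n_markers: int  # supporting (non-missing) markers
    n_discordant: int  # non-missing markers whose raw call disagrees with the label


def haldane_r(distance_bp: float, rho: float) -> float:
    """Recombination fraction over a physical distance via the Haldane map."""
    d_morgans = distance_bp * rho * 1e-8
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def stationary_distribution(params: HmmParams) -> np.ndarray:
    h = params.het_prior
    return np.array([(1.0 - h) / 2.0, (1.0 - h) / 2.0, h])


def transition_matrix(distance_bp: float, params: HmmParams) -> np.ndarray:
    """3x3 state-transition matrix over one inter-marker gap.

    Constructed as T = (1 - a) I + a (1 pi^T) with pi the stationary
    distribution and a = 2 r / (1 - het_prior), which makes the P1->P2 entry
    exactly the Haldane recombination fraction r and scales entry into HET by
    its stationary weight. Rows sum to 1; distance 0 gives the identity.
    """
    if distance_bp < 0:
        raise ConfigError("distance_bp must be >= 0")
    r = haldane_r(distance_bp, params.rho)
    pi = stationary_distribution(params)
    a = 2.0 * r / (1.0 - params.het_prior)
    T = (1.0 - a) * np.eye(3) + a * np.tile(pi, (3, 1))
    # at saturation (r -> 1/2) a diagonal entry can underflow to -1e-16
    return np.maximum(T, 0.0)


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def emission_log_matrix(params: HmmParams) -> np.ndarray:
    """log P(observed call | state), states x {P1, P2, HET, MISSING}."""
    e = np.full((3, 4), params.eps / 2.0)
    for i in range(3):
        e[i, i] = 1.0 - params.eps
    e[:, 3] = 1.0  # MISSING is uninformative
    return _log(e)


def _encode(calls: Sequence[str]) -> np.ndarray:
    try:
        return np.array([_OBS_INDEX[str(c)] for c in calls], dtype=np.intp)
    except KeyError as exc:  # pragma: no cover - contract violation
        raise ValueError(f"unknown origin call {exc.args[0]!r}") from exc


def viterbi_path(
    calls: Sequence[str], positions: Sequence[int], params: HmmParams | None = None
) -> np.ndarray:
    """Maximum-a-posteriori state path over {P1, P2, HET}.

    Ties are broken by remaining in the previous state; at the first marker
    P1 is preferred over P2 over HET.
    """
    params = params or HmmParams()
    if len(calls) != len(positions):
        raise ValueError("calls and positions must have the same length")
    n = len(calls)
    if n == 0:
        return np.array([], dtype="<U7")
    pos = np.asarray(positions, dtype=np.int64)
    if n > 1 and not np.all(np.diff(pos) > 0):
        raise ValueError("positions must be strictly increasing")
    obs = _encode(calls)
    log_e = emission_log_matrix(params)
    delta = _log(stationary_distribution(params)) + log_e[:, obs[0]]
    back = np.zeros((n, 3), dtype=np.intp)
    for t in range(1, n):
        log_t = _log(transition_matrix(float(pos[t] - pos[t - 1]), params))
        scores = delta[:, None] + log_t  # scores[i, j]: from i to j
        best = np.argmax(scores, axis=0)  # first index wins ties (P1 < P2 < HET)
        # prefer staying in the same state on exact ties
        for j in range(3):
            if scores[j, j] >= scores[best[j], j]:
                best[j] = j
        back[t] = best
        delta = scores[best, np.arange(3)] + log_e[:, obs[t]]
    path = np.empty(n, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return np.array([_STATES[i] for i in path], dtype="<U7")


def path_joint_logprob(
    path_labels: Sequence[str],
    calls: Sequence[str],
    positions: Sequence[int],
    params: HmmParams | None = None,
) -> float:
    """Joint log probability of a given state path and the observed calls."""
    params = params or HmmParams()
    obs = _encode(calls)
    states = np.array([_STATE_INDEX[str(s)] for s in path_labels], dtype=np.intp)
    pos = np.asarray(positions, dtype=np.int64)
    log_e = emission_log_matrix(params)
    lp = float(_log(stationary_distribution(params))[states[0]] + log_e[states[0], obs[0]])
    for t in range(1, len(states)):
        log_t = _log(transition_matrix(float(pos[t] - pos[t - 1]), params))
        lp += float(log_t[states[t - 1], states[t]] + log_e[states[t], obs[t]])
    return lp


def windowed_vote_path(
    calls: Sequence[str], window: int = 11
) -> np.ndarray:
    """Majority-vote smoother over a sliding marker window (cross-check only)."""
    if window < 1 or window % 2 == 0:
        raise ConfigError("window must be a positive odd number")
    n = len(calls)
    half = window // 2
    out = np.empty(n, dtype="<U7")
    arr = np.asarray(calls, dtype="<U7")
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        votes = [c for c in arr[lo:hi] if c != MISSING]
        if not votes:
            out[i] = P1
            continue
        counts = {s: votes.count(s) for s in _STATES}
        out[i] = max(_STATES, key=lambda s: counts[s])
    return out


@dataclass
class _Run:
    label: str
    i0: int  # first marker index (inclusive)
    i1: int  # last marker index (inclusive)
    n_markers: int


def _runs_from_path(path: np.ndarray, informative: np.ndarray) -> list[_Run]:
    runs: list[_Run] = []
    for i, label in enumerate(path):
        if runs and runs[-1].label == label:
            runs[-1].i1 = i
            runs[-1].n_markers += int(informative[i])
        else:
            runs.append(_Run(str(label), i, i, int(informative[i])))
    return runs


def _merge_small_runs(runs: list[_Run], min_markers: int) -> list[_Run]:
    """Merge under-supported runs into the better-supported flank until stable.

    The weakest run (leftmost on ties) is absorbed by the flank with greater
    marker support (left flank on ties); adjacent same-label runs coalesce.
    """

    def coalesce(rs: list[_Run]) -> list[_Run]:
        out: list[_Run] = []
        for r in rs:
            if out and out[-1].label == r.label:
                out[-1].i1 = r.i1
                out[-1].n_markers += r.n_markers
            else:
                out.append(r)
        return out

    runs = coalesce(runs)
    while len(runs) > 1:
        weakest = min(range(len(runs)), key=lambda k: (runs[k].n_markers, k))
        if runs[weakest].n_markers >= min_markers:
            break
        left = runs[weakest - 1] if weakest > 0 else None
        right = runs[weakest + 1] if weakest < len(runs) - 1 else None
        if right is None or (left is not None and left.n_markers >= right.n_markers):
            target = weakest - 1
        else:
            target = weakest + 1
        runs[target].n_markers += runs[weakest].n_markers
        runs[target].i0 = min(runs[target].i0, runs[weakest].i0)
        runs[target].i1 = max(runs[target].i1, runs[weakest].i1)
        del runs[weakest]
        runs = coalesce(runs)
    return runs


def path_to_blocks(
    path: Sequence[str],
    positions: Sequence[int],
    params: HmmParams | None = None,
    raw_calls: Sequence[str] | None = None,
    line: str = "",
    chromosome: str = "",
) -> list[Block]:
    """Cut a state path into ordered, merged blocks.

    Maximal constant-label runs become blocks bounded by their first and last
    marker; blocks with fewer than ``min_block_markers`` supporting markers
    are merged into their better-supported flank (left on ties, recursively
    until stable); adjacent same-label blocks coalesce. ``n_discordant`` is
    recomputed against the raw calls.
    """
    params = params or HmmParams()
    n = len(path)
    if n == 0:
        return []
    pos = np.asarray(positions, dtype=np.int64)
    if len(pos) != n:
        raise ValueError("path and positions must be aligned")
    raw = np.asarray(raw_calls, dtype="<U7") if raw_calls is not None else None
    informative = (
        raw != MISSING if raw is not None else np.ones(n, dtype=bool)
    )
    runs = _runs_from_path(np.asarray(path, dtype="<U7"), informative)
    runs = _merge_small_runs(runs, params.min_block_markers)
    blocks: list[Block] = []
    for r in runs:
        if raw is not None:
            inside = raw[r.i0 : r.i1 + 1]
            n_disc = int(np.sum((inside != MISSING) & (inside != r.label)))
        else:
            n_disc = 0
        blocks.append(
            Block(
                line=line,
                chromosome=chromosome,
                start=int(pos[r.i0]),
                end=int(pos[r.i1]),
                label=r.label,
                n_markers=r.n_markers,
                n_discordant=n_disc,
            )
        )
    return blocks


def call_blocks(
    calls_by_chrom: Mapping[str, tuple[Sequence[int], Sequence[str]]],
    params: HmmParams | None = None,
    line: str = "",
) -> list[Block]:
    """Viterbi + block extraction per chromosome for one line.

    ``calls_by_chrom`` maps chromosome -> (marker positions, raw origin calls).
    Chromosomes are processed independently; a chromosome without markers
    yields no blocks and a logged warning.
    """
    params = params or HmmParams()
    blocks: list[Block] = []
    for chrom in calls_by_chrom:
        positions, raw = calls_by_chrom[chrom]
        if len(positions) == 0:
            logger.warning("chromosome %s has no markers; no blocks called", chrom)
            continue
        path = viterbi_path(raw, positions, params)
        blocks.extend(
            path_to_blocks(path, positions, params, raw_calls=raw, line=line, chromosome=chrom)
        )
    return blocks


BLOCK_TSV_COLUMNS = ["line", "chrom", "start", "end", "label", "n_markers", "n_discordant"]


def write_blocks_tsv(path: str, blocks: Sequence[Block]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(BLOCK_TSV_COLUMNS)
        for b in blocks:
            w.writerow([b.line, b.chromosome, b.start, b.end, b.label, b.n_markers, b.n_discordant])


def read_blocks_tsv(path: str) -> list[Block]:
    out: list[Block] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                Block(
                    line=row["line"],
                    chromosome=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    label=row["label"],
                    n_markers=int(row["n_markers"]),
                    n_discordant=int(row["n_discordant"]),
                )
            )
    return out


def write_blocks_bed(path: str, blocks: Sequence[Block]) -> None:
    """Blocks as BED: 0-based half-open, name column ``line:label``."""
    with open(path, "w", newline="") as fh:
        for b in blocks:
            fh.write(f"{b.chromosome}\t{b.start - 1}\t{b.end}\t{b.line}:{b.label}\t{b.n_markers}\t+\n")


def blocks_to_marker_labels(
    blocks: Sequence[Block], positions: Sequence[int], chromosome: str
) -> np.ndarray:
    """Label each marker position from a line's blocks; gaps between blocks -> NA."""
    from ._util import NA

    out = np.full(len(positions), NA, dtype="<U7")
    pos = np.asarray(positions, dtype=np.int64)
    for b in blocks:
        if b.chromosome != chromosome:
            continue
        mask = (pos >= b.start) & (pos <= b.end)
        out[mask] = b.label
    return out


def painting_matrix(
    blocks_by_line: Mapping[str, Sequence[Block]],
    positions: Sequence[int],
    chromosome: str,
):
    """Marker x line label matrix (graphical genotype) for one chromosome."""
    import pandas as pd

    data = {
        line: blocks_to_marker_labels(blocks, positions, chromosome)
        for line, blocks in blocks_by_line.items()
    }
    return pd.DataFrame(data, index=list(positions))
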
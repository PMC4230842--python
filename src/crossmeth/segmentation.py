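"""Two-state HMM segmentation of a methylome into methylated regions (MRs).

Each covered cytosine is in either an unmethylated (U) or methylated (M)
hidden state. Emissions are beta-binomial on the (n_meth, n_total) read
counts, with a separate (alpha, beta) pair per state and per sequence
context (CG, CHG, CHH) -- plant methylomes need all three contexts, unlike
the single-distribution mammalian case. The chain runs over consecutive
covered cytosines (not base pairs); the genome is first split wherever 50
adjacent base pairs lack a covered cytosine, so regions can never span
coverage deserts. After genome-wide Baum-Welch training, Viterbi decoding
yields maximal runs of the M state; these are trimmed at both ends by
removing boundary cytosines with methylation rate below 10%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import betabinom
from .io import CONTEXTS, Region, SampleKey, SampleTable

logger = logging.getLogger(__name__)

STATES = ("U", "M")
LOG_FLOOR = math.log(1e-300)

_CTX_INDEX = {c: i for i, c in enumerate(CONTEXTS)}


@dataclass
class HmmParams:
    """Two-state HMM parameters.

    ``emis[s, c]`` is the (alpha, beta) beta-binomial pair for state ``s``
    (0 = U, 1 = M) and context index ``c`` (CG, CHG, CHH).
    """

    start: np.ndarray
    trans: np.ndarray
    emis: np.ndarray  # shape (2, 3, 2)

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.emis = np.asarray(self.emis, dtype=float)
        if self.start.shape != (2,) or self.trans.shape != (2, 2):
            raise ValueError("start must be length 2 and trans 2x2")
        if self.emis.shape != (2, 3, 2):
            raise ValueError("emis must have shape (2, 3, 2)")
        if not np.allclose(self.trans.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of trans must sum to 1")
        if not np.isclose(self.start.sum(), 1.0, atol=1e-9):
            raise ValueError("start must sum to 1")
        if (self.emis <= 0).any():
            raise ValueError("beta-binomial parameters must be positive")

    @property
    def state_means(self) -> np.ndarray:
        """Per-state, per-context emission mean alpha/(alpha+beta); shape (2, 3)."""
        a = self.emis[..., 0]
        b = self.emis[..., 1]
        return a / (a + b)

    @classmethod
    def default_init(
        cls,
        u_mean: float = 0.05,
        m_mean: float = 0.7,
        concentration: float = 10.0,
        stay: float = 0.9,
    ) -> "HmmParams":
        """Weakly informative, well-separated initialization."""
        emis = np.empty((2, 3, 2))
        for c in range(3):
            emis[0, c] = (u_mean * concentration, (1 - u_mean) * concentration)
            emis[1, c] = (m_mean * concentration, (1 - m_mean) * concentration)
        trans = np.array([[stay, 1 - stay], [1 - stay, stay]])
        return cls(start=np.array([0.5, 0.5]), trans=trans, emis=emis)

    def to_dict(self) -> dict:
        return {
            "start": self.start.tolist(),
            "trans": self.trans.tolist(),
            "emis": {
                STATES[s]: {CONTEXTS[c]: self.emis[s, c].tolist() for c in range(3)}
                for s in range(2)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParams":
        emis = np.empty((2, 3, 2))
        for s, sname in enumerate(STATES):
            for c, cname in enumerate(CONTEXTS):
                emis[s, c] = d["emis"][sname][cname]
        return cls(start=np.array(d["start"]), trans=np.array(d["trans"]), emis=emis)


@dataclass
class Segment:
    """A run of covered cytosines uninterrupted by a >= max_gap coverage gap."""

    chrom: str
    pos: np.ndarray  # 1-based positions, ascending
    strand: np.ndarray
    context_idx: np.ndarray  # index into CONTEXTS
    n_total: np.ndarray
    n_meth: np.ndarray

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def rates(self) -> np.ndarray:
        return self.n_meth / self.n_total


@dataclass
class MethylatedRegion(Region):
    """An MR: maximal M-state run, with per-context count summaries."""

    sample: SampleKey | None = None
    pos: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    context_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    n_total: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    n_meth: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_cytosines_by_context(self) -> dict[str, int]:
        return {c: int(np.sum(self.context_idx == i)) for i, c in enumerate(CONTEXTS)}

    @property
    def mean_rate_by_context(self) -> dict[str, float]:
        out = {}
        for i, c in enumerate(CONTEXTS):
            sel = self.context_idx == i
            out[c] = (
                float(np.sum(self.n_meth[sel]) / np.sum(self.n_total[sel]))
                if sel.any()
                else float("nan")
            )
        return out


def split_segments(table: SampleTable, max_gap: int = 50) -> list[Segment]:
    """Split covered cytosines into segments at coverage gaps.

    A new segment starts whenever >= ``max_gap`` consecutive base pairs lack
    a covered cytosine (on either strand); chromosome boundaries always
    split. Sites with zero coverage never enter a segment.
    """
    df = table.records[table.records["n_total"] > 0]
    segments: list[Segment] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        # number of uncovered base pairs between consecutive covered cytosines
        uncovered = np.diff(np.unique(pos)) - 1
        breaks_at = np.unique(pos)[:-1][uncovered >= max_gap]
        # assign each record to a block by its position relative to breaks
        block = np.searchsorted(breaks_at, pos, side="left")
        for b in np.unique(block):
            sel = block == b
            s = sub[sel]
            segments.append(
                Segment(
                    chrom=str(chrom),
                    pos=s["pos"].to_numpy(),
                    strand=s["strand"].to_numpy(),
                    context_idx=s["context"].map(_CTX_INDEX).to_numpy(),
                    n_total=s["n_total"].to_numpy(),
                    n_meth=s["n_meth"].to_numpy(),
                )
            )
    return segments


def _emission_loglik(seg: Segment, params: HmmParams) -> np.ndarray:
    """Per-site log emission likelihoods, shape (len(seg), 2); floored."""
    ll = np.empty((len(seg), 2))
    for s in range(2):
        for c in range(3):
            sel = seg.context_idx == c
            if sel.any():
                a, b = params.emis[s, c]
                ll[sel, s] = betabinom.logpmf(seg.n_meth[sel], seg.n_total[sel], a, b)
    return np.maximum(ll, LOG_FLOOR)


def _forward_backward(
    logem: np.ndarray, log_start: np.ndarray, log_trans: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Log-space forward-backward for 2 states.

    Returns (gamma, xi_sum, loglik): posterior state probabilities per site,
    summed expected transition counts (2x2), and the segment log-likelihood.
    """
    n = logem.shape[0]
    la = np.empty((n, 2))
    lb = np.empty((n, 2))
    la[0] = log_start + logem[0]
    for t in range(1, n):
        prev = la[t - 1]
        for j in range(2):
            x0 = prev[0] + log_trans[0, j]
            x1 = prev[1] + log_trans[1, j]
            m = x0 if x0 > x1 else x1
            la[t, j] = m + math.log(math.exp(x0 - m) + math.exp(x1 - m)) + logem[t, j]
    lb[n - 1] = 0.0
    for t in range(n - 2, -1, -1):
        nxt = lb[t + 1] + logem[t + 1]
        for i in range(2):
            x0 = log_trans[i, 0] + nxt[0]
            x1 = log_trans[i, 1] + nxt[1]
            m = x0 if x0 > x1 else x1
            lb[t, i] = m + math.log(math.exp(x0 - m) + math.exp(x1 - m))
    last = la[n - 1]
    m = max(last)
    loglik = m + math.log(math.exp(last[0] - m) + math.exp(last[1] - m))
    gamma = np.exp(la + lb - loglik)
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((2, 2))
    if n > 1:
        # vectorised over t: xi[t,i,j] ∝ alpha[t,i] + trans[i,j] + em[t+1,j] + beta[t+1,j]
        for i in range(2):
            for j in range(2):
                v = la[:-1, i] + log_trans[i, j] + logem[1:, j] + lb[1:, j] - loglik
                xi_sum[i, j] = np.exp(v).sum()
    return gamma, xi_sum, float(loglik)


def segment_loglik(seg: Segment, params: HmmParams) -> float:
    """Total log-likelihood of a segment under the model."""
    logem = _emission_loglik(seg, params)
    with np.errstate(divide="ignore"):
        _, _, ll = _forward_backward(
            logem, np.log(params.start), np.log(params.trans)
        )
    return ll


def train_hmm(
    segments: list[Segment],
    init: HmmParams | None = None,
    max_iter: int = 30,
    tol: float = 1e-3,
    mstep_newton_iter: int = 50,
) -> tuple[HmmParams, list[float]]:
    """Baum-Welch (EM) over all segments jointly.

    E-step: log-space forward-backward per segment with context-selected
    beta-binomial emissions. M-step: transition/start updates from expected
    counts; each (alpha, beta) from a posterior-weighted method-of-moments
    estimate refined by Newton iteration (capped at ``mstep_newton_iter``).
    Returns trained parameters and the (non-decreasing) log-likelihood trace.
    """
    segments = [s for s in segments if len(s) > 0]
    if not any(len(s) >= 2 for s in segments):
        raise ValueError("need at least one segment with >= 2 cytosines")
    params = init if init is not None else HmmParams.default_init()
    if all((s.n_meth == 0).all() and (s.n_total == 0).all() for s in segments):
        logger.warning("degenerate data (all counts zero); returning initialization")
        return params, []
    trace: list[float] = []
    for it in range(max_iter):
        with np.errstate(divide="ignore"):
            log_start = np.log(np.maximum(params.start, 1e-300))
            log_trans = np.log(np.maximum(params.trans, 1e-300))
        total_ll = 0.0
        start_acc = np.zeros(2)
        xi_acc = np.zeros((2, 2))
        gammas: list[np.ndarray] = []
        for seg in segments:
            logem = _emission_loglik(seg, params)
            gamma, xi, ll = _forward_backward(logem, log_start, log_trans)
            total_ll += ll
            start_acc += gamma[0]
            xi_acc += xi
            gammas.append(gamma)
        trace.append(total_ll)
        if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
            break
        # M-step
        new_start = start_acc / start_acc.sum()
        row = xi_acc.sum(axis=1, keepdims=True)
        new_trans = np.where(row > 0, xi_acc / np.maximum(row, 1e-300), params.trans)
        new_trans /= new_trans.sum(axis=1, keepdims=True)
        new_emis = params.emis.copy()
        all_k = np.concatenate([s.n_meth for s in segments])
        all_n = np.concatenate([s.n_total for s in segments])
        all_c = np.concatenate([s.context_idx for s in segments])
        all_g = np.concatenate(gammas, axis=0)
        for s in range(2):
            for c in range(3):
                sel = all_c == c
                if not sel.any():
                    continue
                w = all_g[sel, s]
                if w.sum() < 1e-8:
                    continue
                a0, b0 = betabinom.moment_init(all_k[sel], all_n[sel], w)
                a, b = betabinom.fit_mle(
                    all_k[sel],
                    all_n[sel],
                    weights=w,
                    init=(a0, b0),
                    max_iter=mstep_newton_iter,
                )
                new_emis[s, c] = (a, b)
        params = HmmParams(start=new_start, trans=new_trans, emis=new_emis)
    return params, trace


def viterbi(seg: Segment, params: HmmParams) -> np.ndarray:
    """Most probable state path (0 = U, 1 = M) for one segment."""
    logem = _emission_loglik(seg, params)
    with np.errstate(divide="ignore"):
        log_start = np.log(np.maximum(params.start, 1e-300))
        log_trans = np.log(np.maximum(params.trans, 1e-300))
    n = len(seg)
    delta = log_start + logem[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        nd = np.empty(2)
        for j in range(2):
            x0 = delta[0] + log_trans[0, j]
            x1 = delta[1] + log_trans[1, j]
            if x0 >= x1:  # ties resolved toward U for determinism
                nd[j] = x0 + logem[t, j]
                back[t, j] = 0
            else:
                nd[j] = x1 + logem[t, j]
                back[t, j] = 1
        delta = nd
    path = np.empty(n, dtype=np.int8)
    path[-1] = 0 if delta[0] >= delta[1] else 1
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def posterior_decode(seg: Segment, params: HmmParams) -> np.ndarray:
    """Per-site argmax of posterior state probability (alternative decoder)."""
    logem = _emission_loglik(seg, params)
    with np.errstate(divide="ignore"):
        gamma, _, _ = _forward_backward(
            logem, np.log(np.maximum(params.start, 1e-300)),
            np.log(np.maximum(params.trans, 1e-300)),
        )
    return (gamma[:, 1] > 0.5).astype(np.int8)


def decode_mrs(
    segments: list[Segment],
    params: HmmParams,
    sample: SampleKey | None = None,
    decoder: str = "viterbi",
) -> list[MethylatedRegion]:
    """Decode each segment and emit maximal M-state runs as (untrimmed) MRs.

    Region boundaries span the first to last cytosine of the run
    (0-based half-open).
    """
    decode = viterbi if decoder == "viterbi" else posterior_decode
    regions: list[MethylatedRegion] = []
    for seg in segments:
        if len(seg) == 0:
            continue
        path = decode(seg, params)
        t = 0
        n = len(path)
        while t < n:
            if path[t] == 1:
                u = t
                while u + 1 < n and path[u + 1] == 1:
                    u += 1
                sel = slice(t, u + 1)
                k = seg.n_meth[sel]
                nt = seg.n_total[sel]
                regions.append(
                    MethylatedRegion(
                        chrom=seg.chrom,
                        start=int(seg.pos[t] - 1),
                        end=int(seg.pos[u]),
                        rate=float(k.sum() / nt.sum()) if nt.sum() else 0.0,
                        sample=sample,
                        pos=seg.pos[sel].copy(),
                        context_idx=seg.context_idx[sel].copy(),
                        n_total=nt.copy(),
                        n_meth=k.copy(),
                    )
                )
                t = u + 1
            else:
                t += 1
    return regions


def trim_mr(region: MethylatedRegion, min_rate: float = 0.10) -> MethylatedRegion | None:
    """Trim boundary cytosines with methylation rate below ``min_rate``.

    Removal iterates from both ends; the region is dropped (None) if no
    cytosine survives.
    """
    rates = np.divide(
        region.n_meth,
        region.n_total,
        out=np.zeros(len(region.pos)),
        where=region.n_total > 0,
    )
    lo, hi = 0, len(region.pos)
    while lo < hi and rates[lo] < min_rate:
        lo += 1
    while hi > lo and rates[hi - 1] < min_rate:
        hi -= 1
    if lo >= hi:
        return None
    if lo == 0 and hi == len(region.pos):
        return region
    sel = slice(lo, hi)
    k = region.n_meth[sel]
    nt = region.n_total[sel]
    return MethylatedRegion(
        chrom=region.chrom,
        start=int(region.pos[lo] - 1),
        end=int(region.pos[hi - 1]),
        rate=float(k.sum() / nt.sum()) if nt.sum() else 0.0,
        sample=region.sample,
        pos=region.pos[sel].copy(),
        context_idx=region.context_idx[sel].copy(),
        n_total=nt.copy(),
        n_meth=k.copy(),
    )


def segment_methylome(
    table: SampleTable,
    init: HmmParams | None = None,
    max_gap: int = 50,
    trim_rate: float = 0.10,
    max_iter: int = 30,
    tol: float = 1e-3,
) -> tuple[list[MethylatedRegion], HmmParams, list[float]]:
    """Full per-sample pipeline: split -> train -> decode -> trim."""
    segments = split_segments(table, max_gap=max_gap)
    params, trace = train_hmm(segments, init=init, max_iter=max_iter, tol=tol)
    raw = decode_mrs(segments, params, sample=table.key)
    trimmed = [r for r in (trim_mr(r, min_rate=trim_rate) for r in raw) if r is not None]
    return trimmed, params, trace
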
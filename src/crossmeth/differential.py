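"""Differential methylation at site (DMP) and region (DMR) level.

DMPs: two-sided Fisher's exact test on methylated/unmethylated read counts,
restricted to the four sanctioned within-species comparisons (root vs shoot
at each temperature; control vs cold within each tissue) and prefiltered to
sites reaching a 20% methylation rate in at least one of the two samples.

DMRs: candidate intervals where the per-sample methylated-region (MR) sets
disagree are tested with a beta-binomial likelihood-ratio statistic -- per
context, (alpha, beta) is fitted to each sample and to the pool, and the
summed log-odds 2*LOD is referred to chi-squared with 2 degrees of freedom
per context present. Samples are partitioned into groups by the pairwise
tests, counts are combined within groups, and the candidate is confirmed by
re-testing the combined groups. Storey q-values over confirmation p-values
define DMRs at FDR < 0.01; overlapping DMRs are resolved by keeping the
maximum-weight non-overlapping subset (weight = number of significantly
differential samples).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import betabinom
from .calling import SITE_INDEX
from .io import CONTEXTS, Region, SampleKey, SampleTable
from .segmentation import MethylatedRegion

logger = logging.getLogger(__name__)

_CTX_INDEX = {c: i for i, c in enumerate(CONTEXTS)}


@dataclass(frozen=True)
class Comparison:
    """One sanctioned within-species comparison (exactly one factor differs)."""

    sample_a: SampleKey
    sample_b: SampleKey

    def __post_init__(self) -> None:
        a, b = self.sample_a, self.sample_b
        if a.species != b.species:
            raise ValueError("comparisons are within species")
        diff_tissue = a.tissue != b.tissue
        diff_treat = a.treatment != b.treatment
        if diff_tissue == diff_treat:
            raise ValueError("exactly one of tissue/treatment must differ")

    @property
    def axis(self) -> str:
        return "tissue" if self.sample_a.tissue != self.sample_b.tissue else "treatment"

    def label(self) -> str:
        a, b = self.sample_a, self.sample_b
        if self.axis == "tissue":
            return f"{a.tissue}-{a.treatment}_vs_{b.tissue}-{b.treatment}"
        return f"{a.tissue}-{a.treatment}_vs_{b.tissue}-{b.treatment}"


def sanctioned_comparisons(keys: list[SampleKey]) -> list[Comparison]:
    """The four relevant comparisons among the four combined samples:
    root vs shoot at 23C, root vs shoot at 4C, 23C vs 4C in root, in shoot."""
    by_combo = {k.combination: k for k in keys}
    if len(by_combo) != 4:
        raise ValueError("need all four tissue-treatment combinations")
    pairs = [
        (("root", "control23"), ("shoot", "control23")),
        (("root", "cold4"), ("shoot", "cold4")),
        (("root", "control23"), ("root", "cold4")),
        (("shoot", "control23"), ("shoot", "cold4")),
    ]
    return [Comparison(by_combo[a], by_combo[b]) for a, b in pairs]


# ---------------------------------------------------------------------------
# DMPs
# ---------------------------------------------------------------------------


def call_dmps(
    comparison: Comparison,
    table_a: SampleTable,
    table_b: SampleTable,
    min_rate: float = 0.20,
    alpha: float = 0.05,
    min_cov: int = 3,
) -> pd.DataFrame:
    """Fisher's exact DMP test for one comparison.

    Sites covered >= ``min_cov`` in both samples are eligible; only those
    with max(rate_a, rate_b) >= ``min_rate`` are tested (the prefilter that
    keeps the multiple-testing burden down). q-values are BH over tested
    sites within the comparison. ``direction`` is sign(rate_a - rate_b).
    """
    a = table_a.records.set_index(SITE_INDEX)
    b = table_b.records.set_index(SITE_INDEX)
    j = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    n_lost = len(a) + len(b) - 2 * len(j)
    if n_lost:
        logger.info("%s: %d sites absent in one sample skipped", comparison.label(), n_lost)
    covered = (j["n_total_a"] >= min_cov) & (j["n_total_b"] >= min_cov)
    j = j[covered]
    na = j["n_total_a"].to_numpy(np.int64)
    nb = j["n_total_b"].to_numpy(np.int64)
    ka = j["n_meth_a"].to_numpy(np.int64)
    kb = j["n_meth_b"].to_numpy(np.int64)
    ra = ka / na
    rb = kb / nb
    tested = np.fmax(ra, rb) >= min_rate
    p = np.full(len(j), np.nan)
    q = np.full(len(j), np.nan)
    if tested.any():
        idx = np.flatnonzero(tested)
        pv = np.empty(len(idx))
        for ii, i in enumerate(idx):
            pv[ii] = stats.fisher_exact(
                [[ka[i], na[i] - ka[i]], [kb[i], nb[i] - kb[i]]]
            )[1]
        p[idx] = pv
        q[idx] = multipletests(pv, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "context": j["context_a"].to_numpy(),
            "n_meth_a": ka,
            "n_total_a": na,
            "n_meth_b": kb,
            "n_total_b": nb,
            "rate_a": ra,
            "rate_b": rb,
            "tested": tested,
            "p": p,
            "q": q,
            "direction": np.sign(ra - rb).astype(int),
            "is_dmp": tested & (q <= alpha),
        },
        index=j.index,
    ).reset_index()
    out.insert(3, "comparison", comparison.label())
    out.insert(4, "axis", comparison.axis)
    return out


# ---------------------------------------------------------------------------
# DMR candidates
# ---------------------------------------------------------------------------


@dataclass
class DmrCandidate:
    """A disjoint interval of the flattened MR union with discordant presence."""

    chrom: str
    start: int
    end: int
    present_in: frozenset[SampleKey]
    n_shared_cytosines: int = 0


def select_dmr_candidates(
    mrs_by_sample: dict[SampleKey, list[MethylatedRegion]],
    tables: dict[SampleKey, SampleTable],
    min_c: int = 4,
    min_cov: int = 1,
) -> list[DmrCandidate]:
    """Flatten the union of per-sample MRs into disjoint candidate intervals.

    An interval qualifies iff at least one sample's MR covers it, at least
    one sample's does not, and it contains >= ``min_c`` cytosines covered
    (>= ``min_cov`` reads) in *all* samples. Adjacent atomic intervals with
    identical presence patterns are merged.
    """
    keys = sorted(mrs_by_sample, key=lambda k: k.label())
    n_samples = len(keys)
    chroms = sorted({r.chrom for regs in mrs_by_sample.values() for r in regs})
    # per-site coverage intersection across samples
    shared: dict[str, np.ndarray] = {}
    for chrom in chroms:
        pos_sets = []
        for k in keys:
            rec = tables[k].records
            sel = (rec["chrom"] == chrom) & (rec["n_total"] >= min_cov)
            pos_sets.append(set(rec.loc[sel, "pos"]))
        common = set.intersection(*pos_sets) if pos_sets else set()
        shared[chrom] = np.array(sorted(common), dtype=np.int64)

    candidates: list[DmrCandidate] = []
    for chrom in chroms:
        events: list[int] = []
        per_sample: list[list[tuple[int, int]]] = []
        for k in keys:
            ivs = [(r.start, r.end) for r in mrs_by_sample[k] if r.chrom == chrom]
            per_sample.append(sorted(ivs))
            for s, e in ivs:
                events += [s, e]
        bounds = sorted(set(events))
        atoms: list[tuple[int, int, frozenset]] = []
        for s, e in zip(bounds, bounds[1:]):
            present = frozenset(
                keys[i]
                for i, ivs in enumerate(per_sample)
                if any(a <= s and e <= b for a, b in ivs)
            )
            if 0 < len(present) < n_samples:
                atoms.append((s, e, present))
        # merge adjacent atoms with identical presence
        merged: list[tuple[int, int, frozenset]] = []
        for s, e, pres in atoms:
            if merged and merged[-1][1] == s and merged[-1][2] == pres:
                merged[-1] = (merged[-1][0], e, pres)
            else:
                merged.append((s, e, pres))
        pos = shared[chrom]
        for s, e, pres in merged:
            # 1-based site p occupies base p-1; p in [s, e) <=> s+1 <= p <= e
            n_c = int(
                np.searchsorted(pos, e, side="right")
                - np.searchsorted(pos, s + 1, side="left")
            )
            if n_c >= min_c:
                candidates.append(DmrCandidate(chrom, s, e, pres, n_c))
    return candidates


def _region_counts(
    table: SampleTable, chrom: str, start: int, end: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_meth, n_total, context_idx) for covered sites inside [start, end)."""
    rec = table.records
    sel = (
        (rec["chrom"] == chrom)
        & (rec["pos"] - 1 >= start)
        & (rec["pos"] - 1 < end)
        & (rec["n_total"] > 0)
    )
    sub = rec[sel]
    return (
        sub["n_meth"].to_numpy(np.int64),
        sub["n_total"].to_numpy(np.int64),
        sub["context"].map(_CTX_INDEX).to_numpy(np.int64),
    )


def betabinom_lrt(
    counts: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> tuple[float, int, float]:
    """Beta-binomial log-odds test comparing k samples to their pool.

    ``counts`` holds (n_meth, n_total, context_idx) per sample. Per context
    present, (alpha, beta) is ML-fitted to each sample's sites and to the
    pooled sites; LOD_c = sum_g l_g - l_joint; LOD = sum_c LOD_c;
    df = 2 * (k - 1) * n_contexts; p = chi2.sf(2 * LOD, df).
    """
    k = len(counts)
    if k < 2:
        raise ValueError("need at least two samples")
    lod = 0.0
    n_ctx = 0
    for c in range(3):
        per = [(km[ci == c], nm[ci == c]) for km, nm, ci in counts]
        if not all(len(n) > 0 for _, n in per):
            continue
        n_ctx += 1
        ll_sep = 0.0
        for km, nm in per:
            a, b = betabinom.fit_mle(km, nm)
            ll_sep += betabinom.loglik(km, nm, a, b)
        kj = np.concatenate([km for km, _ in per])
        nj = np.concatenate([nm for _, nm in per])
        aj, bj = betabinom.fit_mle(kj, nj)
        lod += ll_sep - betabinom.loglik(kj, nj, aj, bj)
    if n_ctx == 0:
        return 0.0, 1, 1.0
    lod = max(lod, 0.0)
    df = 2 * (k - 1) * n_ctx
    p = float(stats.chi2.sf(2.0 * lod, df))
    return float(lod), df, p


def test_dmr(
    candidate: DmrCandidate,
    table_a: SampleTable,
    table_b: SampleTable,
) -> tuple[float, int, float]:
    """Pairwise beta-binomial log-odds test for one candidate region."""
    ca = _region_counts(table_a, candidate.chrom, candidate.start, candidate.end)
    cb = _region_counts(table_b, candidate.chrom, candidate.start, candidate.end)
    if len(ca[1]) == 0 or len(cb[1]) == 0:
        raise ValueError("candidate has no covered cytosine in one sample")
    return betabinom_lrt([ca, cb])


@dataclass
class DmrResult:
    region: Region
    groups: list[frozenset[SampleKey]]
    pairwise_p: dict[tuple[SampleKey, SampleKey], float]
    lod: float = float("nan")
    df: int = 0
    p: float = float("nan")
    q: float = float("nan")
    status: str = "tested"  # tested | confirmed | filtered
    n_sig_samples: int = 0
    nontransitive: bool = False
    mean_rates: dict[SampleKey, float] = field(default_factory=dict)


def group_and_confirm(
    candidate: DmrCandidate,
    tables: dict[SampleKey, SampleTable],
    pair_alpha: float = 0.01,
) -> DmrResult:
    """Partition the four samples by pairwise significance and re-test groups.

    Sanctioned pairs with p >= ``pair_alpha`` are greedily merged
    (single linkage / union-find): connected samples form a group. If all
    samples fall into one group the candidate is filtered. Otherwise read
    counts are summed within groups and the same log-odds test is run
    between the combined groups; that p-value is the candidate's
    confirmation p. Non-transitive pairwise patterns are resolved by the
    greedy rule and flagged.
    """
    keys = sorted(tables, key=lambda k: k.label())
    comps = sanctioned_comparisons(keys)
    pairwise_p: dict[tuple[SampleKey, SampleKey], float] = {}
    for comp in comps:
        _, _, p = test_dmr(candidate, tables[comp.sample_a], tables[comp.sample_b])
        pairwise_p[(comp.sample_a, comp.sample_b)] = p

    parent = {k: k for k in keys}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), p in sorted(pairwise_p.items(), key=lambda kv: (-kv[1], kv[0][0].label())):
        if p >= pair_alpha:
            parent[find(a)] = find(b)
    groups_map: dict[SampleKey, set[SampleKey]] = {}
    for k in keys:
        groups_map.setdefault(find(k), set()).add(k)
    groups = sorted(
        (frozenset(g) for g in groups_map.values()),
        key=lambda g: sorted(k.label() for k in g)[0],
    )
    # non-transitivity: a significant pair ended up in the same group
    nontrans = any(
        p < pair_alpha and find(a) == find(b) for (a, b), p in pairwise_p.items()
    )
    if nontrans:
        logger.info(
            "candidate %s:%d-%d: non-transitive pairwise significance, greedy grouping",
            candidate.chrom, candidate.start, candidate.end,
        )
    sig_samples = {
        s for (a, b), p in pairwise_p.items() if p < pair_alpha for s in (a, b)
    }
    mean_rates = {}
    for k in keys:
        km, nm, _ = _region_counts(tables[k], candidate.chrom, candidate.start, candidate.end)
        mean_rates[k] = float(km.sum() / nm.sum()) if nm.sum() else float("nan")
    region = Region(
        candidate.chrom,
        candidate.start,
        candidate.end,
        name="dmr_candidate",
        rate=float(np.nanmean(list(mean_rates.values()))),
    )
    if len(groups) == 1:
        return DmrResult(
            region=region,
            groups=groups,
            pairwise_p=pairwise_p,
            status="filtered",
            n_sig_samples=len(sig_samples),
            nontransitive=nontrans,
            mean_rates=mean_rates,
        )
    # combine counts within groups, re-test between groups
    group_counts = []
    for g in groups:
        ks = np.concatenate(
            [
                _region_counts(tables[k], candidate.chrom, candidate.start, candidate.end)[0]
                for k in sorted(g, key=lambda x: x.label())
            ]
        )
        ns = np.concatenate(
            [
                _region_counts(tables[k], candidate.chrom, candidate.start, candidate.end)[1]
                for k in sorted(g, key=lambda x: x.label())
            ]
        )
        cs = np.concatenate(
            [
                _region_counts(tables[k], candidate.chrom, candidate.start, candidate.end)[2]
                for k in sorted(g, key=lambda x: x.label())
            ]
        )
        group_counts.append((ks, ns, cs))
    lod, df, p = betabinom_lrt(group_counts)
    return DmrResult(
        region=region,
        groups=groups,
        pairwise_p=pairwise_p,
        lod=lod,
        df=df,
        p=p,
        status="tested",
        n_sig_samples=len(sig_samples),
        nontransitive=nontrans,
        mean_rates=mean_rates,
    )


def call_dmrs(
    mrs_by_sample: dict[SampleKey, list[MethylatedRegion]],
    tables: dict[SampleKey, SampleTable],
    fdr: float = 0.01,
    pair_alpha: float = 0.01,
    min_c: int = 4,
) -> list[DmrResult]:
    """Full DMR pipeline: candidates -> group/confirm -> Storey FDR -> overlaps.

    Returns all candidate results; those with ``status == "confirmed"``
    (q < ``fdr`` and surviving overlap resolution) are the DMRs.
    """
    candidates = select_dmr_candidates(mrs_by_sample, tables, min_c=min_c)
    results = [group_and_confirm(c, tables, pair_alpha=pair_alpha) for c in candidates]
    tested = [r for r in results if r.status == "tested"]
    if tested:
        q = storey_fdr(np.array([r.p for r in tested]))
        for r, qi in zip(tested, q):
            r.q = float(qi)
            if qi < fdr:
                r.status = "confirmed"
            else:
                r.status = "filtered"
    confirmed = [r for r in results if r.status == "confirmed"]
    kept = resolve_overlaps(
        [(r.region, r.n_sig_samples) for r in confirmed]
    )
    kept_ids = {id(reg) for reg, _ in kept}
    for r in confirmed:
        if id(r.region) not in kept_ids:
            r.status = "filtered"
    return results


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------


def storey_fdr(
    pvals: np.ndarray,
    lambdas: np.ndarray | None = None,
    pi0: float | None = None,
) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a lambda grid
    (0.05 ... 0.95, step 0.05); a cubic smoother is evaluated at the largest
    lambda and clamped to (0, 1]. q_i = min_{p_j >= p_i} pi0 * m * p_j /
    rank(p_j), monotone in p. With fewer than 100 p-values pi0 falls back
    to 1 (BH-equivalent) with a warning; ``pi0`` may also be forced.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    if m == 0:
        return np.empty(0)
    if pi0 is None:
        if m < 100:
            warnings.warn("fewer than 100 p-values: using pi0 = 1 (BH-equivalent)")
            pi0 = 1.0
        else:
            if lambdas is None:
                lambdas = np.arange(0.05, 0.96, 0.05)
            pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
            coef = np.polyfit(lambdas, pi0_l, deg=3)
            pi0 = float(np.polyval(coef, lambdas.max()))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    m_arr = np.arange(1, m + 1)
    q_ranked = pi0 * m * ranked / m_arr
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q_ranked = np.minimum(q_ranked, 1.0)
    q = np.empty(m)
    q[order] = q_ranked
    return q


# ---------------------------------------------------------------------------
# overlap resolution
# ---------------------------------------------------------------------------


def resolve_overlaps(
    weighted_regions: list[tuple[Region, int]],
    exhaustive_limit: int = 20,
) -> list[tuple[Region, int]]:
    """Maximum-weight non-overlapping subset among mutually overlapping DMRs.

    Within each connected overlap cluster the optimum is found by
    exhaustive search (clusters are small in practice); the objective is
    lexicographic: total weight, then total length, then leftmost starts.
    Clusters larger than ``exhaustive_limit`` fall back to weight-then-length
    dynamic programming.
    """
    by_chrom: dict[str, list[tuple[Region, int]]] = {}
    for reg, w in weighted_regions:
        by_chrom.setdefault(reg.chrom, []).append((reg, w))
    kept: list[tuple[Region, int]] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda t: (t[0].start, t[0].end))
        # split into connected overlap clusters
        clusters: list[list[tuple[Region, int]]] = []
        cur: list[tuple[Region, int]] = []
        cur_end = -1
        for reg, w in items:
            if cur and reg.start >= cur_end:
                clusters.append(cur)
                cur = []
            cur.append((reg, w))
            cur_end = max(cur_end, reg.end)
        if cur:
            clusters.append(cur)
        for cluster in clusters:
            if len(cluster) == 1:
                kept.append(cluster[0])
            elif len(cluster) <= exhaustive_limit:
                kept.extend(_best_subset_exhaustive(cluster))
            else:
                kept.extend(_best_subset_dp(cluster))
    return sorted(kept, key=lambda t: (t[0].chrom, t[0].start))


def _subset_key(subset: list[tuple[Region, int]]):
    weight = sum(w for _, w in subset)
    length = sum(len(r) for r, _ in subset)
    starts = tuple(sorted(r.start for r, _ in subset))
    # higher weight, then longer, then leftmost starts (smaller tuple wins)
    return (weight, length, tuple(-s for s in starts))


def _best_subset_exhaustive(cluster: list[tuple[Region, int]]):
    n = len(cluster)
    best: list[tuple[Region, int]] = []
    best_key = (float("-inf"),)
    for mask in range(1, 1 << n):
        subset = [cluster[i] for i in range(n) if mask >> i & 1]
        ok = all(
            not a[0].overlaps(b[0]) for a, b in combinations(subset, 2)
        )
        if not ok:
            continue
        key = _subset_key(subset)
        if key > best_key:
            best_key = key
            best = subset
    return best


def _best_subset_dp(cluster: list[tuple[Region, int]]):
    """Weighted interval scheduling (weight, then length) for large clusters."""
    items = sorted(cluster, key=lambda t: t[0].end)
    n = len(items)
    starts = [r.start for r, _ in items]
    ends = [r.end for r, _ in items]
    import bisect

    pred = [bisect.bisect_right(ends, starts[i]) - 1 for i in range(n)]
    val: list[tuple[int, int]] = [(0, 0)] * (n + 1)
    take: list[bool] = [False] * n
    for i in range(n):
        w, ln = items[i][1], len(items[i][0])
        skip = val[i]
        prev = val[pred[i] + 1]
        with_i = (prev[0] + w, prev[1] + ln)
        if with_i > skip:
            val[i + 1] = with_i
            take[i] = True
        else:
            val[i + 1] = skip
    out = []
    i = n - 1
    while i >= 0:
        if take[i]:
            out.append(items[i])
            i = pred[i]
        else:
            i -= 1
    return out[::-1]
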
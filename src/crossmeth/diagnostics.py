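"""Self-checks: brute-force oracles, calibration runs, recovery studies.

Every routine here recomputes a quantity two ways -- the pipeline's
implementation against an independent brute-force/enumeration oracle, or a
simulation with known truth against the recovered estimate -- and returns
plain numbers. The test suite asserts on them; the acceptance script
reports them. None of these routines is used by the pipeline itself.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from . import betabinom, calling, differential, expression, segmentation, simulate
from .io import SampleKey, SampleTable
from .segmentation import HmmParams, Segment

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def fisher_two_sided_oracle(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher p by exhaustive table enumeration.

    Fixes the margins of [[k1, n1-k1], [k2, n2-k2]] and sums the
    (central hypergeometric) probabilities of all tables with point
    probability <= that of the observed table (the point-probability rule).
    """
    col1 = k1 + k2  # methylated margin
    N = n1 + n2

    def log_table_prob(a: int) -> float:
        # a = top-left cell; hypergeometric with N, col1, n1
        return (
            gammaln(col1 + 1)
            - gammaln(a + 1)
            - gammaln(col1 - a + 1)
            + gammaln(N - col1 + 1)
            - gammaln(n1 - a + 1)
            - gammaln(N - col1 - (n1 - a) + 1)
            - (gammaln(N + 1) - gammaln(n1 + 1) - gammaln(N - n1 + 1))
        )

    lo = max(0, col1 - n2)
    hi = min(col1, n1)
    lp_obs = log_table_prob(k1)
    total = 0.0
    for a in range(lo, hi + 1):
        lp = log_table_prob(a)
        if lp <= lp_obs + 1e-9:  # tolerance for float ties
            total += math.exp(lp)
    return min(total, 1.0)


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct tail summation."""

    def log_pmf(i: int) -> float:
        return (
            gammaln(K + 1)
            - gammaln(i + 1)
            - gammaln(K - i + 1)
            + gammaln(N - K + 1)
            - gammaln(n - i + 1)
            - gammaln(N - K - (n - i) + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
        )

    lo = max(k, 0, n - (N - K))
    hi = min(K, n)
    return min(sum(math.exp(log_pmf(i)) for i in range(lo, hi + 1)), 1.0)


def viterbi_bruteforce(seg: Segment, params: HmmParams) -> np.ndarray:
    """Argmax over all 2^n state paths (independent emission route via scipy)."""
    n = len(seg)
    em = np.empty((n, 2))
    for s in range(2):
        for c in range(3):
            sel = seg.context_idx == c
            if sel.any():
                a, b = params.emis[s, c]
                em[sel, s] = betabinom.scipy_logpmf(
                    seg.n_meth[sel], seg.n_total[sel], a, b
                )
    em = np.maximum(em, segmentation.LOG_FLOOR)
    with np.errstate(divide="ignore"):
        ls = np.log(np.maximum(params.start, 1e-300))
        lt = np.log(np.maximum(params.trans, 1e-300))
    best_path = None
    best_score = -np.inf
    for path in product((0, 1), repeat=n):
        score = ls[path[0]] + em[0, path[0]]
        for t in range(1, n):
            score += lt[path[t - 1], path[t]] + em[t, path[t]]
        if score > best_score + 1e-12:
            best_score = score
            best_path = path
    return np.array(best_path, dtype=np.int8)


def segment_loglik_bruteforce(seg: Segment, params: HmmParams) -> float:
    """Total likelihood by explicit summation over all 2^n paths."""
    n = len(seg)
    em = np.empty((n, 2))
    for s in range(2):
        for c in range(3):
            sel = seg.context_idx == c
            if sel.any():
                a, b = params.emis[s, c]
                em[sel, s] = betabinom.scipy_logpmf(
                    seg.n_meth[sel], seg.n_total[sel], a, b
                )
    scores = []
    with np.errstate(divide="ignore"):
        ls = np.log(np.maximum(params.start, 1e-300))
        lt = np.log(np.maximum(params.trans, 1e-300))
    for path in product((0, 1), repeat=n):
        score = ls[path[0]] + em[0, path[0]]
        for t in range(1, n):
            score += lt[path[t - 1], path[t]] + em[t, path[t]]
        scores.append(score)
    m = max(scores)
    return m + math.log(sum(math.exp(s - m) for s in scores))


def random_segment(rng: np.random.Generator, n_max: int = 12) -> Segment:
    n = int(rng.integers(2, n_max + 1))
    n_total = rng.integers(1, 30, size=n)
    return Segment(
        chrom="chr1",
        pos=np.cumsum(rng.integers(1, 20, size=n)).astype(np.int64),
        strand=np.array(["+"] * n),
        context_idx=rng.integers(0, 3, size=n),
        n_total=n_total,
        n_meth=rng.binomial(n_total, rng.random(n)),
    )


def random_params(rng: np.random.Generator) -> HmmParams:
    emis = rng.uniform(0.2, 20.0, size=(2, 3, 2))
    t = rng.uniform(0.05, 0.95)
    u = rng.uniform(0.05, 0.95)
    s = rng.uniform(0.05, 0.95)
    return HmmParams(
        start=np.array([s, 1 - s]),
        trans=np.array([[t, 1 - t], [u, 1 - u]]),
        emis=emis,
    )


# ---------------------------------------------------------------------------
# oracle-equivalence sweeps
# ---------------------------------------------------------------------------


def fisher_oracle_sweep(max_total: int = 30) -> float:
    """Max |scipy two-sided Fisher p - enumeration oracle| over all 2x2
    tables with n1 + n2 <= max_total."""
    worst = 0.0
    for n1 in range(1, max_total):
        for n2 in range(1, max_total - n1 + 1):
            for k1 in range(n1 + 1):
                for k2 in range(n2 + 1):
                    p_impl = stats.fisher_exact(
                        [[k1, n1 - k1], [k2, n2 - k2]]
                    )[1]
                    p_or = fisher_two_sided_oracle(k1, n1, k2, n2)
                    worst = max(worst, abs(p_impl - p_or))
    return worst


def viterbi_oracle_sweep(n_instances: int = 200, seed: int = 0) -> float:
    """Fraction of random small segments where Viterbi == brute-force argmax."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        seg = random_segment(rng)
        params = random_params(rng)
        if np.array_equal(segmentation.viterbi(seg, params), viterbi_bruteforce(seg, params)):
            agree += 1
    return agree / n_instances


def hypergeom_oracle_sweep(n_instances: int = 200, seed: int = 0) -> float:
    """Max |scipy hypergeometric sf - tail-sum oracle| on random setups."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        N = int(rng.integers(10, 200))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        k = int(rng.integers(0, min(K, n) + 1))
        p_impl = float(stats.hypergeom.sf(k - 1, N, K, n))
        worst = max(worst, abs(p_impl - hypergeom_tail_oracle(k, N, K, n)))
    return worst


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def site_pvalue_superuniformity(
    n_sites: int = 10_000, fmr: float = 0.005, mean_cov: float = 20.0, seed: int = 0
) -> float:
    """D+ = sup_t (ECDF(t) - t) of null site p-values.

    Unmethylated sites at the true conversion-failure rate give discrete,
    conservative (super-uniform) p-values: the ECDF must stay at or below
    the diagonal, so the one-sided Kolmogorov statistic D+ is the relevant
    calibration measure; anti-conservativeness shows up as D+ above the
    sampling band.
    """
    rng = np.random.default_rng(seed)
    n_total = rng.poisson(mean_cov, size=n_sites)
    n_total = np.maximum(n_total, 1)
    n_meth = rng.binomial(n_total, fmr)
    p = calling.binomial_pvalues(n_meth, n_total, fmr)
    ps = np.sort(p)
    ecdf_hi = np.arange(1, n_sites + 1) / n_sites
    return float(np.max(ecdf_hi - ps))


def dmr_null_type1(
    n_regions: int = 10_000,
    n_sites: int = 20,
    mean_cov: float = 20.0,
    a: float = 2.0,
    b: float = 8.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the beta-binomial region test under the null.

    Both samples' counts are drawn from one beta-binomial; the fraction of
    regions with p < alpha estimates the realized size of the chi-squared
    approximation.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_regions):
        ctx = rng.integers(0, 3, size=2 * n_sites)
        n = np.maximum(rng.poisson(mean_cov, size=2 * n_sites), 1)
        k = betabinom.rvs(n, a, b, rng)
        ca = (k[:n_sites], n[:n_sites], ctx[:n_sites])
        cb = (k[n_sites:], n[n_sites:], ctx[n_sites:])
        _, _, p = differential.betabinom_lrt([ca, cb])
        if p < alpha:
            hits += 1
    return hits / n_regions


def glm_null_type1(
    n_genes: int = 2000, alpha: float = 0.05, dispersion: float = 0.1, seed: int = 0
) -> dict[str, float]:
    """Per-term type-I error of the NB GLM deviance ANOVA on null genes."""
    design = simulate.expression_design("speciesA", n_replicates=3)
    counts, _ = simulate.simulate_expression(
        n_genes, design, dispersion=dispersion, seed=seed
    )
    disp = expression.estimate_dispersion(counts, design)
    fits = expression.fit_and_test(counts, design, disp)
    out = {}
    for term in ("tissue", "treatment", "tissue:treatment"):
        p = fits[f"p_{term}"].dropna()
        out[term] = float((p < alpha).mean())
    return out


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------


def hmm_recovery(
    genome_length: int = 30_000,
    mean_cov: float = 20.0,
    seed: int = 0,
    max_iter: int = 30,
) -> dict[str, float]:
    """Train on one simulated methylome; report emission-mean error and
    base-level F1 of called MRs against the true M blocks."""
    _, catalogue = simulate.simulate_genome(1, genome_length, seed=seed)
    truth_params = simulate.default_true_params()
    key = SampleKey("sim", "root", "control23", 1)
    tables, truth = simulate.simulate_methylome(
        catalogue, params=truth_params, mean_cov=mean_cov, fmr=0.005,
        design=[key], seed=seed + 1,
    )
    table = tables[key]
    segs = segmentation.split_segments(table)
    params, trace = segmentation.train_hmm(segs, max_iter=max_iter)
    # states are exchangeable: align by CG emission mean
    means = params.state_means
    order = np.argsort(means[:, 0])
    mean_err = float(np.max(np.abs(means[order] - truth_params.state_means)))
    regions = segmentation.decode_mrs(segs, params)
    if order[1] == 0:  # decoder labelled states swapped; recompute via swap
        swapped = HmmParams(
            start=params.start[::-1].copy(),
            trans=params.trans[::-1, ::-1].copy(),
            emis=params.emis[::-1].copy(),
        )
        regions = segmentation.decode_mrs(segs, swapped)
    called = np.zeros(genome_length, dtype=bool)
    for r in regions:
        called[r.start : r.end] = True
    sp = truth.state_path
    true_mask = np.zeros(genome_length, dtype=bool)
    m_pos = sp.loc[sp["state"] == 1, "pos"].to_numpy()
    blocks = _runs_to_intervals(sp["pos"].to_numpy(), sp["state"].to_numpy())
    for s, e in blocks:
        true_mask[s:e] = True
    tp = float(np.sum(called & true_mask))
    prec = tp / max(called.sum(), 1)
    rec = tp / max(true_mask.sum(), 1)
    f1 = 2 * prec * rec / max(prec + rec, 1e-12)
    block_hit = 0
    for s, e in blocks:
        inter = np.sum(called[s:e])
        if inter >= 0.5 * (e - s):
            block_hit += 1
    return {
        "emission_mean_max_abs_error": mean_err,
        "mr_base_f1": float(f1),
        "true_block_recall_50pct": block_hit / max(len(blocks), 1),
        "n_true_blocks": float(len(blocks)),
        "loglik_monotone": float(
            all(b >= a - 1e-6 for a, b in zip(trace, trace[1:]))
        ),
        "n_m_sites": float(len(m_pos)),
    }


def _runs_to_intervals(pos: np.ndarray, state: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of state 1 -> half-open base intervals (first..last site)."""
    out = []
    i, n = 0, len(state)
    while i < n:
        if state[i] == 1:
            j = i
            while j + 1 < n and state[j + 1] == 1:
                j += 1
            out.append((int(pos[i] - 1), int(pos[j])))
            i = j + 1
        else:
            i += 1
    return out


def fmr_recovery(
    fmr_true: float = 0.005, n_reads: int = 100_000, seed: int = 0
) -> dict[str, float]:
    """Spike-in FMR estimate vs truth, in binomial standard errors."""
    rng = np.random.default_rng(seed)
    n_sites = max(1, n_reads // 20)
    n_total = np.maximum(rng.poisson(20, size=n_sites), 1)
    n_meth = rng.binomial(n_total, fmr_true)
    spike = pd.DataFrame(
        {
            "chrom": "lambda",
            "pos": np.arange(1, n_sites + 1),
            "strand": "+",
            "context": "CHH",
            "n_total": n_total,
            "n_meth": n_meth,
        }
    )
    est = calling.estimate_fmr(spike)
    total = float(n_total.sum())
    se = math.sqrt(fmr_true * (1 - fmr_true) / total)
    return {
        "fmr_estimate": est.fmr,
        "fmr_true": fmr_true,
        "abs_error_in_se": abs(est.fmr - fmr_true) / se,
    }


def dispersion_recovery(
    true_dispersion: float = 0.4, n_genes: int = 500, seed: int = 0
) -> dict[str, float]:
    design = simulate.expression_design("speciesA", n_replicates=3)
    counts, _ = simulate.simulate_expression(
        n_genes, design, dispersion=true_dispersion, seed=seed
    )
    est = expression.estimate_dispersion(counts, design)
    med = float(np.nanmedian(est))
    return {
        "dispersion_true": true_dispersion,
        "dispersion_median_estimate": med,
        "relative_error": (
            med / true_dispersion - 1.0 if true_dispersion > 0 else float("nan")
        ),
    }


# ---------------------------------------------------------------------------
# end-to-end scaled study
# ---------------------------------------------------------------------------


def run_study(
    genome_length: int = 100_000,
    mean_cov: float = 20.0,
    fmr: float = 0.005,
    n_dmrs: int = 20,
    dmr_length: int = 400,
    dmr_delta: float = 0.7,
    seed: int = 0,
    hmm_max_iter: int = 20,
) -> dict[str, float]:
    """One-species, four-combination, two-replicate study with injected
    tissue DMRs and no treatment effects, run through the whole pipeline.

    Reports DMP/DMR counts per axis, confirmed-DMR specificity against the
    injected truth, and the realized FDR at the Storey 0.01 threshold.
    """
    _, catalogue = simulate.simulate_genome(1, genome_length, seed=seed)
    design = simulate.factorial_design("sim", n_replicates=2)
    spacing = genome_length // (n_dmrs + 1)
    dmr_spec = [
        simulate.InjectedDmr(
            "chr1", (i + 1) * spacing, (i + 1) * spacing + dmr_length, "shoot", dmr_delta
        )
        for i in range(n_dmrs)
    ]
    tables, truth = simulate.simulate_methylome(
        catalogue,
        mean_cov=mean_cov,
        fmr=fmr,
        design=design,
        dmr_spec=dmr_spec,
        seed=seed + 1,
    )
    # replicate merge per combination
    combined: dict[SampleKey, SampleTable] = {}
    for combo in sorted({k.combination for k in design}):
        reps = sorted(
            (k for k in design if k.combination == combo), key=lambda k: k.replicate
        )
        t1, t2 = tables[reps[0]], tables[reps[1]]
        f1 = calling.estimate_fmr(t1.spikein).fmr
        f2 = calling.estimate_fmr(t2.spikein).fmr
        merged, _ = calling.merge_replicates(t1, t2, f1, f2)
        combined[merged.key] = merged

    # DMPs over the four sanctioned comparisons
    keys = sorted(combined, key=lambda k: k.label())
    comps = differential.sanctioned_comparisons(keys)
    dmp_counts = {"tissue": 0, "treatment": 0}
    for comp in comps:
        res = differential.call_dmps(
            comp, combined[comp.sample_a], combined[comp.sample_b]
        )
        dmp_counts[comp.axis] += int(res["is_dmp"].sum())

    # MRs per combination, then the DMR pipeline
    mrs_by_sample = {}
    for k in keys:
        regions, _, _ = segmentation.segment_methylome(
            combined[k], max_iter=hmm_max_iter
        )
        mrs_by_sample[k] = regions
    results = differential.call_dmrs(mrs_by_sample, combined)
    confirmed = [r for r in results if r.status == "confirmed"]

    def axis_of(groups) -> str:
        if len(groups) != 2:
            return "other"
        if all(len({k.tissue for k in g}) == 1 for g in groups):
            return "tissue"
        if all(len({k.treatment for k in g}) == 1 for g in groups):
            return "treatment"
        return "other"

    dmr_axis = {"tissue": 0, "treatment": 0, "other": 0}
    for r in confirmed:
        dmr_axis[axis_of(r.groups)] += 1

    injected = [d.as_region() for d in dmr_spec]
    n_overlap = sum(
        1 for r in confirmed if any(r.region.overlaps(i) for i in injected)
    )
    specificity = n_overlap / len(confirmed) if confirmed else 1.0
    realized_fdr = 1.0 - specificity if confirmed else 0.0
    recovered = sum(
        1 for i in injected if any(r.region.overlaps(i) for r in confirmed)
    )
    return {
        "dmp_tissue": float(dmp_counts["tissue"]),
        "dmp_treatment": float(dmp_counts["treatment"]),
        "dmp_tissue_treatment_ratio": (
            dmp_counts["tissue"] / max(dmp_counts["treatment"], 1)
        ),
        "dmr_confirmed": float(len(confirmed)),
        "dmr_tissue": float(dmr_axis["tissue"]),
        "dmr_treatment": float(dmr_axis["treatment"]),
        "dmr_specificity": specificity,
        "dmr_realized_fdr": realized_fdr,
        "injected_dmr_recall": recovered / len(injected),
        "n_candidates": float(len(results)),
    }


# ---------------------------------------------------------------------------
# comparative classification & determinism
# ---------------------------------------------------------------------------


def classification_check(
    n_sites: int = 20_000, divergence: float = 0.05, seed: int = 0
) -> dict[str, float]:
    """classify_sites vs the generator's own bookkeeping."""
    from . import comparative

    _, catalogue = simulate.simulate_genome(1, 60_000, seed=seed)
    species = ["crub", "alyr", "atha"]
    aligned, truth = simulate.simulate_alignment_map(
        catalogue, species, divergence=divergence, seed=seed + 1, n_sites=n_sites
    )
    classified, tally = comparative.classify_sites(aligned, truth.statuses, species)
    mismatches = 0
    for cls, n_true in truth.tally.items():
        if tally.get(cls, 0) != n_true:
            mismatches += 1
    excluded_impl = set(np.flatnonzero((classified["cons_class"] == "excluded").to_numpy()))
    excluded_true = set(np.flatnonzero(truth.h_to_g.to_numpy()))
    # partition: conserved3 + shared2 + gains + unmethylated == kept & testable
    kept_testable = int((~truth.h_to_g & (truth.true_class != "untestable")).sum())
    part = (
        tally["conserved3"]
        + tally["shared2"]
        + sum(tally[f"gain:{sp}"] for sp in species)
        + tally["unmethylated"]
    )
    losses = sum(tally[f"loss:{sp}"] for sp in species)
    return {
        "tally_mismatches": float(mismatches),
        "exclusion_set_symmetric_difference": float(
            len(excluded_impl ^ excluded_true)
        ),
        "partition_holds": float(part == kept_testable),
        "losses_equal_shared2": float(losses == tally["shared2"]),
        "n_sites": float(len(aligned)),
    }


def determinism_check(seed: int = 0) -> dict[str, float]:
    """Byte-identity of every stochastic stage's output under a fixed seed."""
    import io as _io

    from .io import write_cytosine_table, write_regions_bed

    def one_pass() -> str:
        _, catalogue = simulate.simulate_genome(1, 5_000, seed=seed)
        key = SampleKey("sim", "root", "control23", 1)
        tables, _ = simulate.simulate_methylome(
            catalogue, mean_cov=10, design=[key], seed=seed + 1
        )
        table = tables[key]
        segs = segmentation.split_segments(table)
        params, _ = segmentation.train_hmm(segs, max_iter=5)
        regions = segmentation.decode_mrs(segs, params, sample=key)
        buf = _io.StringIO()
        table.records.to_csv(buf, sep="\t", index=False)
        out = buf.getvalue()
        out += repr(params.to_dict())
        out += "".join(f"{r.chrom}:{r.start}-{r.end};" for r in regions)
        q = differential.storey_fdr(
            np.random.default_rng(seed).uniform(size=500) ** 2
        )
        out += repr(q[:10].tolist())
        return out

    a = one_pass()
    b = one_pass()
    return {"identical": float(a == b)}
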
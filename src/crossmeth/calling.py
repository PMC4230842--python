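"""False-methylation-rate estimation, methylated-site calling, replicate merge.

Bisulfite conversion failure makes unmethylated cytosines look methylated;
its rate (FMR) is estimated from reads on the unmethylated spike-in
("lambda") chromosome. A cytosine is called methylated when a one-sided
binomial test against the FMR survives FDR correction *and* its methylation
rate reaches 20% in at least one of the four tissue-treatment combinations.
Replicates are combined by summing read counts after removing sites that
are differentially methylated between the replicates (Fisher's exact test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SampleKey, SampleTable, sort_records

logger = logging.getLogger(__name__)

SITE_INDEX = ["chrom", "pos", "strand"]


@dataclass
class FmrEstimate:
    """Conversion-failure (false methylation) rate for one sample."""

    sample: SampleKey
    fmr: float
    per_coverage_bin: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fmr <= 1.0:
            raise ValueError(f"fmr must be a probability, got {self.fmr}")


def estimate_fmr(
    spikein: pd.DataFrame,
    sample: SampleKey | None = None,
    coverage_bins: list[int] | None = None,
) -> FmrEstimate:
    """Pooled FMR = sum(n_meth) / sum(n_total) over spike-in records.

    ``coverage_bins`` (bin edges) adds an optional per-coverage-bin table;
    the pooled estimate is what downstream testing uses.
    """
    total = int(spikein["n_total"].sum())
    if total == 0:
        raise ValueError("cannot estimate FMR: zero spike-in reads")
    fmr = float(spikein["n_meth"].sum() / total)
    per_bin = None
    if coverage_bins:
        binned = spikein.assign(
            bin=pd.cut(spikein["n_total"], bins=coverage_bins, right=False)
        )
        grp = binned.groupby("bin", observed=True)[["n_meth", "n_total"]].sum()
        with np.errstate(invalid="ignore"):
            grp["fmr"] = grp["n_meth"] / grp["n_total"]
        per_bin = grp.reset_index()
    key = sample if sample is not None else SampleKey("unknown", "root", "control23", 1)
    return FmrEstimate(sample=key, fmr=fmr, per_coverage_bin=per_bin)


def binomial_pvalues(n_meth: np.ndarray, n_total: np.ndarray, fmr: float) -> np.ndarray:
    """Upper-tail P(X >= n_meth), X ~ Binomial(n_total, fmr).

    With fmr = 0 the tail is 1 for n_meth = 0 and 0 otherwise (conversion
    failure can only inflate apparent methylation, so the test is one-sided).
    """
    n_meth = np.asarray(n_meth)
    n_total = np.asarray(n_total)
    if fmr == 0.0:
        return np.where(n_meth == 0, 1.0, 0.0)
    return stats.binom.sf(n_meth - 1, n_total, fmr)


def call_methylated_sites(
    table: SampleTable,
    fmr: float,
    min_cov: int = 3,
    alpha: float = 0.05,
    min_rate: float = 0.20,
    rates_across_combinations: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-site methylation calls for one (replicate-combined) sample.

    Sites with ``n_total >= min_cov`` are tested (one-sided binomial against
    ``fmr``); q-values are Benjamini-Hochberg over tested sites. A site is
    methylated iff q <= alpha and its maximum rate over the four
    tissue-treatment combinations (``rates_across_combinations``, indexed by
    (chrom, pos, strand); the sample's own rate if None) is >= ``min_rate``.

    Returns a frame with columns rate, p, q, testable, is_methylated
    alongside the site columns.
    """
    df = table.records.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        df["rate"] = np.where(df["n_total"] > 0, df["n_meth"] / df["n_total"], np.nan)
    df["testable"] = df["n_total"] >= min_cov
    df["p"] = np.nan
    df["q"] = np.nan
    tested = df["testable"].to_numpy()
    if tested.any():
        p = binomial_pvalues(
            df.loc[tested, "n_meth"].to_numpy(),
            df.loc[tested, "n_total"].to_numpy(),
            fmr,
        )
        df.loc[tested, "p"] = p
        df.loc[tested, "q"] = multipletests(p, method="fdr_bh")[1]
    if rates_across_combinations is not None:
        idx = pd.MultiIndex.from_frame(df[SITE_INDEX])
        max_rate = rates_across_combinations.reindex(idx).to_numpy()
        max_rate = np.fmax(max_rate, df["rate"].to_numpy())
    else:
        max_rate = df["rate"].to_numpy()
    df["is_methylated"] = (
        tested & (df["q"].to_numpy() <= alpha) & (max_rate >= min_rate)
    )
    return df


def max_rate_across(tables: list[SampleTable], min_cov: int = 3) -> pd.Series:
    """Per-site maximum methylation rate over several (combined) samples.

    Only rates estimated from >= ``min_cov`` reads enter the maximum; this
    implements the "at least 20% in one of the four tissue-treatment
    combinations" rule when passed the four combined samples of one species.
    """
    pieces = []
    for t in tables:
        df = t.records[t.records["n_total"] >= min_cov]
        s = pd.Series(
            (df["n_meth"] / df["n_total"]).to_numpy(),
            index=pd.MultiIndex.from_frame(df[SITE_INDEX]),
        )
        pieces.append(s)
    allr = pd.concat(pieces)
    return allr.groupby(level=[0, 1, 2]).max()


def fisher_pvalues(
    k1: np.ndarray, n1: np.ndarray, k2: np.ndarray, n2: np.ndarray
) -> np.ndarray:
    """Two-sided Fisher's exact p for tables [[k1, n1-k1], [k2, n2-k2]]."""
    out = np.empty(len(k1))
    for i in range(len(k1)):
        out[i] = stats.fisher_exact(
            [[k1[i], n1[i] - k1[i]], [k2[i], n2[i] - k2[i]]], alternative="two-sided"
        )[1]
    return out


def merge_replicates(
    rep1: SampleTable,
    rep2: SampleTable,
    fmr1: float,
    fmr2: float,
    alpha: float = 0.05,
    min_rate: float = 0.20,
    min_cov: int = 3,
) -> tuple[SampleTable, pd.DataFrame]:
    """Combine replicate read counts after removing replicate-discordant sites.

    Sites covered (>= min_cov) in both replicates with rate >= ``min_rate``
    in at least one replicate are tested by Fisher's exact test; those with
    BH q <= alpha are dropped as replicate DMPs. Sites covered in a single
    replicate are retained with that replicate's counts. Returns the
    combined table (replicate index 0) and a small report frame.
    """
    k1, k2 = rep1.key, rep2.key
    if (k1.species, k1.tissue, k1.treatment) != (k2.species, k2.tissue, k2.treatment):
        raise ValueError("replicates must share species, tissue and treatment")
    a = rep1.records.set_index(SITE_INDEX)
    b = rep2.records.set_index(SITE_INDEX)
    joined = a.join(b, how="outer", lsuffix="_1", rsuffix="_2")
    both = joined["n_total_1"].notna() & joined["n_total_2"].notna()
    j = joined[both]
    n1 = j["n_total_1"].to_numpy(float)
    n2 = j["n_total_2"].to_numpy(float)
    m1 = j["n_meth_1"].to_numpy(float)
    m2 = j["n_meth_2"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r1 = np.where(n1 > 0, m1 / n1, 0.0)
        r2 = np.where(n2 > 0, m2 / n2, 0.0)
    testable = (n1 >= min_cov) & (n2 >= min_cov) & (np.fmax(r1, r2) >= min_rate)
    drop = np.zeros(len(j), dtype=bool)
    if testable.any():
        p = fisher_pvalues(
            m1[testable].astype(int),
            n1[testable].astype(int),
            m2[testable].astype(int),
            n2[testable].astype(int),
        )
        q = multipletests(p, method="fdr_bh")[1]
        drop[np.flatnonzero(testable)] = q <= alpha
    n_single = int((~both).sum())
    logger.info(
        "merge %s: %d replicate-DMPs removed, %d single-replicate sites retained",
        k1.label(), int(drop.sum()), n_single,
    )

    merged = joined.copy()
    for col in ("n_total", "n_meth"):
        merged[col] = merged[[f"{col}_1", f"{col}_2"]].fillna(0).sum(axis=1).astype(np.int64)
    ctx = merged["context_1"].fillna(merged["context_2"])
    merged["context"] = ctx
    keep_mask = np.ones(len(merged), dtype=bool)
    keep_mask[np.flatnonzero(both.to_numpy())[drop]] = False
    out = (
        merged.loc[keep_mask, ["context", "n_total", "n_meth"]]
        .reset_index()
        .pipe(sort_records)
    )
    spike = pd.concat([rep1.spikein, rep2.spikein], ignore_index=True)
    spike = (
        spike.groupby(SITE_INDEX + ["context"], as_index=False)[["n_total", "n_meth"]]
        .sum()
        .pipe(sort_records)
    )
    combined = SampleTable(key=k1.combined(), records=out, spikein=spike)
    report = pd.DataFrame(
        {
            "n_sites": [len(merged)],
            "n_tested": [int(testable.sum())],
            "n_replicate_dmps_removed": [int(drop.sum())],
            "n_single_replicate": [n_single],
        }
    )
    return combined, report
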
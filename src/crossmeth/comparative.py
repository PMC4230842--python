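"""Cross-species conservation of methylation and descriptive statistics.

Aligned cytosines (1:1:1 across three genomes) are first filtered by
context matching -- a site is comparable only if its CG/CHG/CHH label is
identical in all three species; H-position substitutions that do not create
a G never change the label, while any substitution to G does, so label
inequality is exactly the exclusion rule. Kept, fully testable sites are
classified: methylated in all three species = conserved; in exactly one =
a lineage-specific gain of that species; in exactly two = a lineage-specific
loss of the unmethylated species. Supporting statistics: windowed
gain-density, CG gene-body methylation, average feature methylation rates,
feature annotation with TE-first precedence, and hypergeometric/permutation
tests of MR or DMR sharing at orthologous genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import Region

CLASS_NAMES = ("conserved3", "shared2", "gain", "loss", "unmethylated", "excluded")

ANNOTATION_PRECEDENCE = (
    "TE",
    "exon",
    "intron",
    "five_prime_UTR",
    "three_prime_UTR",
    "upstream1kb",
    "intergenic",
)


def match_context(contexts: tuple[str, str, str] | list[str]) -> bool:
    """Keep an aligned site iff all three context labels agree.

    Identical CG in all species, or the same degenerate context everywhere
    (H-position differences allowed as long as no H mutated to G -- a G
    mutation always changes the label, so label equality is the whole rule).
    """
    c1, c2, c3 = contexts
    return c1 == c2 == c3


def classify_sites(
    aligned: pd.DataFrame,
    statuses: pd.DataFrame,
    species: list[str],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign each aligned site a conservation class and tally the classes.

    ``aligned`` carries ``context_<sp>`` columns; ``statuses`` carries
    ``status_<sp>`` in {methylated, unmethylated, untestable}. Sites whose
    contexts differ get class ``excluded``; sites untestable in any species
    are omitted from the tally and labelled ``untestable``. Gains and losses
    are suffixed with the species (``gain:<sp>`` / ``loss:<sp>``); two-way
    methylated sites are both ``shared2`` and a loss of the missing species.

    Returns (per-site frame with a ``cons_class`` column, tally dict). The
    tally also reports ``shared2`` (= sum of losses) and the omitted counts.
    """
    ctx = np.stack([aligned[f"context_{sp}"].to_numpy() for sp in species])
    stat = np.stack([statuses[f"status_{sp}"].to_numpy() for sp in species])
    kept = (ctx[0] == ctx[1]) & (ctx[0] == ctx[2])
    untestable = (stat == "untestable").any(axis=0)
    meth = stat == "methylated"
    n_meth = meth.sum(axis=0)

    cls = np.empty(len(aligned), dtype=object)
    cls[~kept] = "excluded"
    om = kept & untestable
    cls[om] = "untestable"
    ok = kept & ~untestable
    cls[ok & (n_meth == 3)] = "conserved3"
    cls[ok & (n_meth == 0)] = "unmethylated"
    for j, sp in enumerate(species):
        gain_j = ok & (n_meth == 1) & meth[j]
        cls[gain_j] = f"gain:{sp}"
        loss_j = ok & (n_meth == 2) & ~meth[j]
        cls[loss_j] = f"loss:{sp}"

    out = aligned.copy()
    out["cons_class"] = cls
    tally: dict[str, int] = {
        "conserved3": int(np.sum(ok & (n_meth == 3))),
        "unmethylated": int(np.sum(ok & (n_meth == 0))),
        "shared2": int(np.sum(ok & (n_meth == 2))),
        "excluded": int(np.sum(~kept)),
        "untestable": int(np.sum(om)),
    }
    for j, sp in enumerate(species):
        tally[f"gain:{sp}"] = int(np.sum(ok & (n_meth == 1) & meth[j]))
        tally[f"loss:{sp}"] = int(np.sum(ok & (n_meth == 2) & ~meth[j]))
    return out, tally


def gain_density(
    classified: pd.DataFrame,
    species: str,
    window: int = 10_000,
) -> pd.DataFrame:
    """Per-window gains / (gains + losses), anchored on one species' coords.

    Windows tile each chromosome; windows without gains or losses are
    omitted (the statistic is undefined there).
    """
    df = classified[classified["cons_class"].astype(str).str.match("gain:|loss:")]
    if df.empty:
        return pd.DataFrame(columns=["chrom", "window_start", "gains", "losses", "density"])
    chrom = df[f"chrom_{species}"]
    wstart = ((df[f"pos_{species}"] - 1) // window) * window
    is_gain = df["cons_class"].str.startswith("gain:")
    grp = pd.DataFrame(
        {"chrom": chrom, "window_start": wstart, "gain": is_gain}
    ).groupby(["chrom", "window_start"])["gain"]
    out = grp.agg(gains="sum", total="count").reset_index()
    out["losses"] = out["total"] - out["gains"]
    out["density"] = out["gains"] / out["total"]
    return out[["chrom", "window_start", "gains", "losses", "density"]]


def gene_body_methylation(
    gene_start: int, gene_end: int, chrom: str, calls: pd.DataFrame
) -> float:
    """Fraction of methylated CG sites within the gene span (ATG to STOP).

    ``calls`` is a site-calling frame (chrom/pos/context/testable/
    is_methylated). Returns NaN when no testable CG site falls in the span.
    """
    sel = (
        (calls["chrom"] == chrom)
        & (calls["pos"] - 1 >= gene_start)
        & (calls["pos"] - 1 < gene_end)
        & (calls["context"] == "CG")
        & calls["testable"]
    )
    sub = calls[sel]
    if len(sub) == 0:
        return float("nan")
    return float(sub["is_methylated"].sum() / len(sub))


def feature_methylation_rate(
    features: list,
    calls: pd.DataFrame,
    context: str,
    normalize_to: float | None = None,
) -> float:
    """Average per-site methylation rate over all testable sites of a context
    inside a feature set, zeros included; NaN if no site qualifies.

    ``normalize_to`` divides by an outgroup species' rate for cross-species
    display.
    """
    mask = np.zeros(len(calls), dtype=bool)
    chroms = calls["chrom"].to_numpy()
    pos0 = calls["pos"].to_numpy() - 1
    for f in features:
        mask |= (chroms == f.chrom) & (pos0 >= f.start) & (pos0 < f.end)
    sel = mask & (calls["context"] == context).to_numpy() & calls["testable"].to_numpy()
    if not sel.any():
        return float("nan")
    rate = float(calls.loc[sel, "rate"].mean())
    if normalize_to is not None:
        rate /= normalize_to
    return rate


def _merged_intervals(features: list, kind: str) -> dict[str, np.ndarray]:
    """Per-chromosome merged (start, end) arrays for one feature kind."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        if f.kind == kind:
            by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64)
    return out


def annotate_sites(
    sites: pd.DataFrame,
    features: list,
    precedence: tuple[str, ...] = ANNOTATION_PRECEDENCE,
) -> pd.Series:
    """One feature label per site by precedence (TE first, intergenic last).

    ``sites`` needs chrom and pos (1-based) columns. Deterministic and
    total: every site receives exactly one label.
    """
    labels = np.full(len(sites), "intergenic", dtype=object)
    undecided = np.ones(len(sites), dtype=bool)
    chroms = sites["chrom"].to_numpy()
    pos0 = sites["pos"].to_numpy() - 1
    for kind in precedence:
        if kind == "intergenic":
            continue
        merged = _merged_intervals(features, kind)
        for chrom, ivs in merged.items():
            cand = undecided & (chroms == chrom)
            if not cand.any():
                continue
            idx = np.searchsorted(ivs[:, 0], pos0[cand], side="right") - 1
            inside = (idx >= 0) & (pos0[cand] < ivs[np.maximum(idx, 0), 1])
            hit = np.flatnonzero(cand)[inside]
            labels[hit] = kind
            undecided[hit] = False
    return pd.Series(labels, index=sites.index, name="feature")


# ---------------------------------------------------------------------------
# ortholog overlap tests
# ---------------------------------------------------------------------------


@dataclass
class OverlapReport:
    """MR/DMR sharing at orthologs: observed counts, tests, permutations."""

    n_orthologs: int
    per_species_counts: dict[str, int]
    pairwise: pd.DataFrame  # species_a, species_b, observed, p_hypergeom
    observed_two_way: int  # orthologs hit in >= 2 species
    observed_three_way: int
    perm_max_two_way: int = 0
    perm_max_three_way: int = 0
    exceeds_two_way: bool = False
    exceeds_three_way: bool = False
    n_permutations: int = 0
    presence: pd.DataFrame = field(default_factory=pd.DataFrame)


def regions_at_orthologs(
    regions: list[Region],
    gene_intervals: pd.DataFrame,
) -> set[str]:
    """Gene ids (from a frame with gene_id, chrom, start, end) overlapping
    at least one region."""
    hit: set[str] = set()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for row in gene_intervals.itertuples():
        for s, e in by_chrom.get(row.chrom, ()):
            if s < row.end and row.start < e:
                hit.add(row.gene_id)
                break
    return hit


def ortholog_overlap_tests(
    regions_by_species: dict[str, list[Region]],
    orthologs: pd.DataFrame,
    gene_intervals_by_species: dict[str, pd.DataFrame],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> OverlapReport:
    """Test MR/DMR co-occurrence at 1:1:1 orthologs.

    Pairwise sharing gets an upper-tail hypergeometric p (overlap of the
    two species' region-bearing ortholog sets out of N orthologs). Two- and
    three-way sharing is compared with the maximum over ``n_permutations``
    random relabellings of region presence across orthologs, independently
    within each species; observed counts exceeding every permutation are
    flagged (the asterisk rule).
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    species = list(orthologs.columns)
    n = len(orthologs)
    presence = pd.DataFrame(index=orthologs.index)
    for sp in species:
        hit = regions_at_orthologs(
            regions_by_species.get(sp, []), gene_intervals_by_species[sp]
        )
        presence[sp] = orthologs[sp].isin(hit)
    counts = {sp: int(presence[sp].sum()) for sp in species}

    rows = []
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            a, b = species[i], species[j]
            obs = int((presence[a] & presence[b]).sum())
            p = float(stats.hypergeom.sf(obs - 1, n, counts[a], counts[b]))
            rows.append({"species_a": a, "species_b": b, "observed": obs, "p_hypergeom": p})
    pairwise = pd.DataFrame(rows)

    hits_per_ortholog = presence.sum(axis=1)
    obs2 = int((hits_per_ortholog >= 2).sum())
    obs3 = int((hits_per_ortholog == 3).sum())

    rng = np.random.default_rng(seed)
    mat = presence.to_numpy()
    max2 = 0
    max3 = 0
    for _ in range(n_permutations):
        perm = np.column_stack(
            [mat[rng.permutation(n), j] for j in range(len(species))]
        )
        s = perm.sum(axis=1)
        max2 = max(max2, int((s >= 2).sum()))
        max3 = max(max3, int((s == 3).sum()))
    return OverlapReport(
        n_orthologs=n,
        per_species_counts=counts,
        pairwise=pairwise,
        observed_two_way=obs2,
        observed_three_way=obs3,
        perm_max_two_way=max2,
        perm_max_three_way=max3,
        exceeds_two_way=obs2 > max2,
        exceeds_three_way=obs3 > max3,
        n_permutations=n_permutations,
        presence=presence,
    )
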
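"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure of a factorial whole-genome bisulfite
study of three related species (2 tissues x 2 treatments x replicates):

* genomes as i.i.d. nucleotide sequence with the standard CG/CHG/CHH
  context assignment on both strands;
* methylomes whose per-cytosine rates follow a two-state (U/M) Markov
  segment structure with context-specific beta-binomial emissions, Poisson
  read depth, and additive conversion-failure noise (observed rate =
  level + (1 - level) * fmr), plus an unmethylated spike-in chromosome at
  the same failure rate;
* injected tissue-specific differentially methylated regions;
* three-way aligned-site maps with context divergence at H positions;
* negative-binomial expression counts under a factorial GLM.

All bookkeeping (state paths, injected regions, class tallies, true
coefficients) is returned alongside the data and serves as the oracle for
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import build_design
from .io import CONTEXTS, SPIKEIN_CHROM, Region, SampleKey, SampleTable, sort_records
from .segmentation import HmmParams

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class InjectedDmr:
    """A tissue-specific methylation shift on a half-open interval."""

    chrom: str
    start: int
    end: int
    tissue: str
    delta: float  # added to the latent level for samples of `tissue`, clipped to [0, 1]

    def as_region(self) -> Region:
        return Region(self.chrom, self.start, self.end, name=f"dmr_{self.tissue}")


@dataclass
class SimTruth:
    """Generator bookkeeping emitted alongside the data."""

    state_path: pd.DataFrame  # chrom, pos, strand, state (0=U, 1=M), level
    true_params: HmmParams
    injected_dmrs: list[InjectedDmr]
    fmr_true: float
    levels_by_combination: dict[tuple[str, str], np.ndarray] = field(
        default_factory=dict
    )


def default_true_params(
    u_mean: float = 0.05,
    m_mean: float = 0.85,
    concentration: float = 12.0,
    stay_u: float = 0.98,
    stay_m: float = 0.95,
) -> HmmParams:
    """A realistic plant-like truth: sparse methylation in long U stretches,
    M blocks of a few dozen cytosines, well-separated state means."""
    emis = np.empty((2, 3, 2))
    for c in range(3):
        emis[0, c] = (u_mean * concentration, (1 - u_mean) * concentration)
        emis[1, c] = (m_mean * concentration, (1 - m_mean) * concentration)
    trans = np.array([[stay_u, 1 - stay_u], [1 - stay_m, stay_m]])
    # stationary distribution of the chain as the start distribution
    pi_m = (1 - stay_u) / ((1 - stay_u) + (1 - stay_m))
    return HmmParams(start=np.array([1 - pi_m, pi_m]), trans=trans, emis=emis)


def simulate_genome(
    n_chrom: int,
    lengths: int | list[int],
    gc: float = 0.36,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """I.i.d. nucleotide chromosomes plus their cytosine context catalogue.

    Every C on the + strand and every G on the + strand (a C on the reverse
    complement) is assigned CG/CHG/CHH by the standard 3-mer rule; cytosines
    too close to a chromosome end to determine their context are skipped.
    """
    if isinstance(lengths, int):
        lengths = [lengths] * n_chrom
    if len(lengths) != n_chrom:
        raise ValueError("need one length per chromosome")
    if min(lengths) < 1000:
        raise ValueError("chromosome lengths must be >= 1 kb")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    rows = []
    for i in range(n_chrom):
        chrom = f"chr{i + 1}"
        seq = "".join(rng.choice(alphabet, size=lengths[i], p=probs))
        seqs[chrom] = seq
        cat = cytosine_contexts(seq)
        cat.insert(0, "chrom", chrom)
        rows.append(cat)
    catalogue = sort_records(pd.concat(rows, ignore_index=True)[["chrom", "pos", "strand", "context"]])
    return seqs, catalogue


def cytosine_contexts(seq: str) -> pd.DataFrame:
    """Context catalogue (pos 1-based, strand, context) for one sequence."""
    rows: list[tuple[int, str, str]] = []
    n = len(seq)
    for i, base in enumerate(seq):
        if base == "C":
            if i + 1 >= n:
                continue
            if seq[i + 1] == "G":
                ctx = "CG"
            elif i + 2 >= n:
                continue
            elif seq[i + 2] == "G":
                ctx = "CHG"
            else:
                ctx = "CHH"
            rows.append((i + 1, "+", ctx))
        elif base == "G":
            # C on the minus strand; its downstream bases are + positions i-1, i-2
            if i - 1 < 0:
                continue
            if seq[i - 1] == "C":
                ctx = "CG"
            elif i - 2 < 0:
                continue
            elif seq[i - 2] == "C":
                ctx = "CHG"
            else:
                ctx = "CHH"
            rows.append((i + 1, "-", ctx))
    return pd.DataFrame(rows, columns=["pos", "strand", "context"])


def factorial_design(
    species: str, n_replicates: int = 2
) -> list[SampleKey]:
    """The four tissue-treatment combinations x replicates for one species."""
    keys = []
    for tissue in ("root", "shoot"):
        for treatment in ("control23", "cold4"):
            for rep in range(1, n_replicates + 1):
                keys.append(SampleKey(species, tissue, treatment, rep))
    return keys


def simulate_methylome(
    catalogue: pd.DataFrame,
    params: HmmParams | None = None,
    mean_cov: float = 20.0,
    fmr: float = 0.005,
    design: list[SampleKey] | None = None,
    dmr_spec: list[InjectedDmr] | None = None,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
    spikein_fraction: float = 1e-3,
) -> tuple[dict[SampleKey, SampleTable], SimTruth]:
    """Draw per-sample count tables from a hidden two-state segment structure.

    The hidden U/M path runs over consecutive cytosines (catalogue order)
    per chromosome; each cytosine gets a latent level from the state- and
    context-specific beta; counts are Binomial(Poisson(mean_cov) reads,
    level + (1 - level) * fmr). Injected DMRs shift the level for samples
    of the designated tissue. Replicates share the latent truth and differ
    only in count noise. A spike-in chromosome (level 0, same failure rate,
    ~``spikein_fraction`` of the catalogue size) is attached to every sample.
    """
    params = params if params is not None else default_true_params()
    if design is None:
        design = factorial_design("speciesA")
    dmr_spec = dmr_spec or []
    for d in dmr_spec:
        limit = (
            chrom_lengths.get(d.chrom)
            if chrom_lengths
            else int(catalogue.loc[catalogue["chrom"] == d.chrom, "pos"].max())
        )
        if limit is None or d.start < 0 or d.end > limit:
            raise ValueError(f"injected DMR {d} outside chromosome bounds")
    rng = np.random.default_rng(seed)
    cat = sort_records(catalogue.copy())
    ctx_idx = cat["context"].map({c: i for i, c in enumerate(CONTEXTS)}).to_numpy()
    n_sites = len(cat)

    # hidden state path per chromosome
    state = np.empty(n_sites, dtype=np.int8)
    for _, idx in cat.groupby("chrom", sort=True).indices.items():
        m = len(idx)
        u = rng.random(m)
        s = 1 if u[0] < params.start[1] else 0
        state[idx[0]] = s
        stay = params.trans
        for t in range(1, m):
            s = 1 if u[t] < stay[state[idx[t - 1]], 1] else 0
            state[idx[t]] = s

    # latent level per site from the state/context beta
    a = params.emis[state, ctx_idx, 0]
    b = params.emis[state, ctx_idx, 1]
    base_level = rng.beta(a, b)

    # per-combination levels (DMR injection is tissue-specific)
    pos = cat["pos"].to_numpy()
    chroms = cat["chrom"].to_numpy()
    levels_by_combination: dict[tuple[str, str], np.ndarray] = {}
    combos = sorted({k.combination for k in design})
    for tissue, treatment in combos:
        lv = base_level.copy()
        for d in dmr_spec:
            if d.tissue != tissue:
                continue
            sel = (chroms == d.chrom) & (pos - 1 >= d.start) & (pos - 1 < d.end)
            lv[sel] = np.clip(lv[sel] + d.delta, 0.0, 1.0)
        levels_by_combination[(tissue, treatment)] = lv

    # spike-in chromosome shared across samples (positions/contexts only)
    n_spike = max(1, int(round(n_sites * spikein_fraction)))
    spike_ctx = rng.choice(len(CONTEXTS), size=n_spike)

    tables: dict[SampleKey, SampleTable] = {}
    for key in design:
        lv = levels_by_combination[key.combination]
        p_obs = lv + (1 - lv) * fmr
        n_total = rng.poisson(mean_cov, size=n_sites)
        n_meth = rng.binomial(n_total, p_obs)
        rec = cat.copy()
        rec["n_total"] = n_total
        rec["n_meth"] = n_meth
        sp_total = rng.poisson(mean_cov, size=n_spike)
        sp_meth = rng.binomial(sp_total, fmr)
        spike = pd.DataFrame(
            {
                "chrom": SPIKEIN_CHROM,
                "pos": np.arange(1, n_spike + 1),
                "strand": "+",
                "context": [CONTEXTS[c] for c in spike_ctx],
                "n_total": sp_total,
                "n_meth": sp_meth,
            }
        )
        tables[key] = SampleTable(key=key, records=rec, spikein=spike)

    truth = SimTruth(
        state_path=pd.DataFrame(
            {
                "chrom": chroms,
                "pos": pos,
                "strand": cat["strand"].to_numpy(),
                "state": state,
                "level": base_level,
            }
        ),
        true_params=params,
        injected_dmrs=list(dmr_spec),
        fmr_true=fmr,
        levels_by_combination=levels_by_combination,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# alignment map
# ---------------------------------------------------------------------------

DEFAULT_CLASS_PROBS = {
    "unmethylated": 0.90,
    "conserved3": 0.02,
    "gain": 0.06,  # split evenly across species
    "loss": 0.02,  # split evenly across species
}


@dataclass
class AlignmentTruth:
    """Per-site truth for a synthetic three-way aligned-site map."""

    statuses: pd.DataFrame  # status_<sp> in {methylated, unmethylated, untestable}
    true_class: pd.Series  # the class classify_sites should recover
    tally: dict[str, int]  # over kept, fully testable sites
    h_to_g: pd.Series  # sites excluded because an H position mutated to G


def simulate_alignment_map(
    catalogue: pd.DataFrame,
    species: list[str],
    divergence: float = 0.05,
    seed: int = 0,
    n_sites: int | None = None,
    class_probs: dict[str, float] | None = None,
    p_untestable: float = 0.02,
) -> tuple[pd.DataFrame, AlignmentTruth]:
    """Mark a subset of anchor-catalogue cytosines as 1:1:1 aligned.

    H-position substitutions are introduced with probability ``divergence``
    per degenerate-context site (one random species, one random replacement
    base); a replacement by G changes the context label (CHH -> CHG or CG,
    CHG -> CG) and such sites must later be excluded by context matching.
    Methylation statuses per species are drawn from ``class_probs``.
    """
    if not 0 <= divergence < 0.5:
        raise ValueError("divergence must be in [0, 0.5)")
    if len(species) != 3:
        raise ValueError("need exactly three species")
    rng = np.random.default_rng(seed)
    probs = dict(class_probs or DEFAULT_CLASS_PROBS)
    cat = catalogue.reset_index(drop=True)
    if n_sites is not None and n_sites < len(cat):
        keep = np.sort(rng.choice(len(cat), size=n_sites, replace=False))
        cat = cat.iloc[keep].reset_index(drop=True)
    m = len(cat)

    ctx = np.tile(cat["context"].to_numpy(), (3, 1))  # per-species labels
    h_to_g = np.zeros(m, dtype=bool)
    degenerate = cat["context"].isin(["CHG", "CHH"]).to_numpy()
    hit = degenerate & (rng.random(m) < divergence)
    for i in np.flatnonzero(hit):
        sp = rng.integers(3)
        old = ctx[sp, i]
        old_h = rng.choice(list("ACT"))  # the anchor H base at the substituted position
        new_base = rng.choice([b for b in "ACGT" if b != old_h])
        if new_base == "G":
            h_to_g[i] = True
            if old == "CHG":
                ctx[sp, i] = "CG"
            else:  # CHH: mutated H position chosen uniformly
                ctx[sp, i] = "CG" if rng.random() < 0.5 else "CHG"
        # substitutions to A/C/T keep the context label

    classes = ["unmethylated", "conserved3"] + [f"gain:{s}" for s in species] + [
        f"loss:{s}" for s in species
    ]
    p = np.array(
        [probs["unmethylated"], probs["conserved3"]]
        + [probs["gain"] / 3] * 3
        + [probs["loss"] / 3] * 3
    )
    p = p / p.sum()
    drawn = rng.choice(len(classes), size=m, p=p)

    status = np.full((3, m), "unmethylated", dtype=object)
    for i, cls_idx in enumerate(drawn):
        cls = classes[cls_idx]
        if cls == "conserved3":
            status[:, i] = "methylated"
        elif cls.startswith("gain:"):
            status[species.index(cls.split(":")[1]), i] = "methylated"
        elif cls.startswith("loss:"):
            sp_u = species.index(cls.split(":")[1])
            status[:, i] = "methylated"
            status[sp_u, i] = "unmethylated"
    untestable = rng.random((3, m)) < p_untestable
    status[untestable] = "untestable"

    # assemble the aligned-site table with per-species coordinates
    data: dict[str, np.ndarray] = {}
    for j, sp in enumerate(species):
        offset = j * 10_000_000  # synthetic coordinate shift per species
        data[f"chrom_{sp}"] = cat["chrom"].to_numpy()
        data[f"pos_{sp}"] = cat["pos"].to_numpy() + offset
        data[f"strand_{sp}"] = cat["strand"].to_numpy()
        data[f"context_{sp}"] = ctx[j]
    aligned = pd.DataFrame(data)

    statuses = pd.DataFrame({f"status_{sp}": status[j] for j, sp in enumerate(species)})
    kept = (ctx[0] == ctx[1]) & (ctx[0] == ctx[2])
    fully_testable = ~untestable.any(axis=0)
    true_class = pd.Series(
        np.where(
            ~kept, "excluded", np.where(~fully_testable, "untestable", np.array(classes)[drawn])
        )
    )
    tally_sel = kept & fully_testable
    tally: dict[str, int] = {}
    for cls in classes:
        tally[cls] = int(np.sum(np.array(classes)[drawn][tally_sel] == cls))
    truth = AlignmentTruth(
        statuses=statuses,
        true_class=true_class,
        tally=tally,
        h_to_g=pd.Series(h_to_g),
    )
    return aligned, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTruth:
    coefficients: pd.DataFrame  # genes x design columns (log scale)
    dispersions: np.ndarray
    de_genes: dict[str, np.ndarray]  # term -> boolean mask of affected genes
    lib_sizes: np.ndarray


def expression_design(
    species: list[str] | str = "speciesA", n_replicates: int = 3
) -> pd.DataFrame:
    """Sample sheet for the expression arm (replicates x 4 combinations)."""
    if isinstance(species, str):
        species = [species]
    rows = []
    for sp in species:
        for tissue in ("root", "shoot"):
            for treatment in ("control23", "cold4"):
                for rep in range(1, n_replicates + 1):
                    rows.append((sp, tissue, treatment, rep))
    return pd.DataFrame(rows, columns=["species", "tissue", "treatment", "replicate"])


def simulate_expression(
    n_genes: int,
    design: pd.DataFrame,
    factors: list[str] | None = None,
    dispersion: float | np.ndarray = 0.1,
    lib_sizes: np.ndarray | float = 2e6,
    effects: dict[str, tuple[int, float]] | None = None,
    baseline_log_mean: tuple[float, float] = (1.0, 6.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """NB counts under a factorial GLM with known coefficients.

    ``effects`` maps a term name (e.g. ``"tissue"`` or ``"tissue:treatment"``)
    to ``(n_affected_genes, log2_fold_change)``; affected genes are disjoint
    blocks in gene order. Counts are gamma-Poisson with gene-wise dispersion.
    """
    factors = factors or [f for f in ("species", "tissue", "treatment") if design[f].nunique() > 1]
    rng = np.random.default_rng(seed)
    X, term_slices = build_design(design, factors)
    n_samples = len(design)
    lib = np.full(n_samples, float(lib_sizes)) if np.isscalar(lib_sizes) else np.asarray(lib_sizes, float)
    disp = (
        np.full(n_genes, float(dispersion))
        if np.isscalar(dispersion)
        else np.asarray(dispersion, float)
    )
    if (disp < 0).any():
        raise ValueError("dispersions must be >= 0")

    p = X.shape[1]
    beta = np.zeros((n_genes, p))
    # baseline: log mean relative to library size (natural-log scale)
    beta[:, 0] = rng.uniform(*baseline_log_mean, size=n_genes) - np.log(lib.mean())
    de_genes: dict[str, np.ndarray] = {}
    cursor = 0
    for term, (n_aff, log2fc) in (effects or {}).items():
        if term not in term_slices:
            raise ValueError(f"unknown term {term!r}; have {list(term_slices)}")
        mask = np.zeros(n_genes, dtype=bool)
        mask[cursor : cursor + n_aff] = True
        cursor += n_aff
        sign = np.where(rng.random(n_aff) < 0.5, -1.0, 1.0)
        for col in term_slices[term]:
            beta[mask, col] = sign * log2fc * np.log(2.0)
        de_genes[term] = mask

    mu = lib[None, :] * np.exp(beta @ X.T)
    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for g in range(n_genes):
        if disp[g] < 1e-8:
            counts[g] = rng.poisson(mu[g])
        else:
            lam = rng.gamma(shape=1.0 / disp[g], scale=mu[g] * disp[g])
            counts[g] = rng.poisson(lam)
    genes = [f"gene{g + 1:05d}" for g in range(n_genes)]
    cols = [
        f"{r.species}_{r.tissue}_{r.treatment}_rep{r.replicate}"
        for r in design.itertuples()
    ]
    counts_df = pd.DataFrame(counts, index=genes, columns=cols)
    truth = ExpressionTruth(
        coefficients=pd.DataFrame(beta, index=genes),
        dispersions=disp,
        de_genes=de_genes,
        lib_sizes=lib,
    )
    return counts_df, truth
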
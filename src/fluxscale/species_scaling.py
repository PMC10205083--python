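"""Cross-species expression screen for body-mass (allometric) scaling.

Finds genes whose liver expression is ordered inversely to adult body
mass across species: counts are normalised (CPM, optionally TMM-scaled),
collapsed to shared reference symbols via an ortholog map, filtered to
the strictly monotone-by-mass pattern (e.g. mouse > rat > monkey >
human > cattle), tested by one-way ANOVA with Bonferroni correction, and
optionally restricted to curated gene sets with a hypergeometric
enrichment test.  The same machinery applies to protein intensity tables
after per-sample median centering (with ANOVA skipped when the design
has single replicates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "normalize_cpm",
    "tmm_factors",
    "collapse_orthologs",
    "monotone_scaling_filter",
    "anova_bonferroni",
    "pathway_filter",
    "gene_set_enrichment",
    "cluster_heatmap_order",
    "median_center_columns",
    "ScalingScreen",
    "ScreenResults",
]


@dataclass
class CountMatrix:
    """Gene x sample count matrix with species and body-mass annotations.

    ``counts`` is a DataFrame indexed by gene id with sample columns;
    ``species_of_sample`` maps each column to a species label and
    ``body_mass_of_species`` each species to its adult mass in grams.
    """

    counts: pd.DataFrame
    species_of_sample: dict[str, str]
    body_mass_of_species: dict[str, float]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.species_of_sample]
        if missing:
            raise ValueError(f"samples without a species label: {missing}")
        species = set(self.species_of_sample[s] for s in self.counts.columns)
        if len(species) < 2:
            raise ValueError("need >= 2 species for a cross-species screen")
        for sp in species:
            mass = self.body_mass_of_species.get(sp)
            if mass is None or mass <= 0:
                raise ValueError(f"species {sp!r} needs a positive body mass")

    @property
    def species_order_by_mass(self) -> list[str]:
        """Species present, smallest body mass first."""
        present = {self.species_of_sample[s] for s in self.counts.columns}
        return sorted(present, key=self.body_mass_of_species.__getitem__)

    def replicates(self, species: str) -> list[str]:
        return [s for s in self.counts.columns
                if self.species_of_sample[s] == species]


class GeneSetCollection(dict):
    """Named gene sets (set name -> frozenset of reference symbols)."""

    def __init__(self, sets: dict[str, set], descriptions: dict[str, str] | None = None):
        for name, members in sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        super().__init__({k: frozenset(v) for k, v in sets.items()})
        self.descriptions = descriptions or {name: "" for name in sets}


def normalize_cpm(counts: pd.DataFrame,
                  tmm: pd.Series | None = None) -> pd.DataFrame:
    """Counts-per-million normalisation, optionally TMM-scaled.

    Each sample's counts are divided by its library size (x 1e6); when
    ``tmm`` factors are given, the effective library size is library
    size x factor, as in standard between-sample count normalisation.
    """
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    if tmm is not None:
        lib = lib * tmm.reindex(lib.index)
    return counts.div(lib, axis=1) * 1e6


def _tmm_pair(obs: np.ndarray, ref: np.ndarray,
              log_ratio_trim: float, abs_expr_trim: float) -> float:
    """Trimmed-mean-of-M-values factor of one sample against the reference."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)  # zeros excluded pairwise
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        raise ValueError("no genes survive pairwise zero exclusion; "
                         "consider smaller trim fractions")
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.allclose(m, 0.0, atol=1e-10):
        return 1.0  # identical relative profiles
    lo_m, hi_m = np.quantile(m, [log_ratio_trim, 1 - log_ratio_trim])
    lo_a, hi_a = np.quantile(a, [abs_expr_trim, 1 - abs_expr_trim])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep.any():
        raise ValueError("no genes survive trimming; "
                         "consider smaller trim fractions")
    # precision weights: inverse asymptotic variance of M
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, reference_sample: str | None = None,
                log_ratio_trim: float = 0.30,
                abs_expr_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors per sample.

    Canonical trim fractions: 30 % on log-ratios (M), 5 % on absolute
    expression (A); weighted by the inverse asymptotic variance of M.
    The reference sample defaults to the one whose upper-quartile
    relative expression is closest to the mean upper quartile.  Factors
    are rescaled so their geometric mean is 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    if reference_sample is None:
        uq = counts.div(lib, axis=1).quantile(0.75)
        reference_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[reference_sample].to_numpy(dtype=float)
    factors = pd.Series(
        {s: _tmm_pair(counts[s].to_numpy(dtype=float), ref,
                      log_ratio_trim, abs_expr_trim)
         for s in counts.columns})
    factors /= np.exp(np.log(factors).mean())  # geometric mean -> 1
    return factors


def collapse_orthologs(matrix: pd.DataFrame, ortholog_map: pd.DataFrame,
                       species_of_sample: dict[str, str],
                       collision_rule: str = "sum",
                       require_all_species: bool = True) -> pd.DataFrame:
    """Collapse per-species gene ids to shared reference symbols.

    ``ortholog_map`` has columns (species, source_gene_id,
    reference_symbol).  Many-to-one collisions within a species are
    resolved by ``collision_rule`` ("sum" preserves total signal; "mean"
    available).  With ``require_all_species`` symbols absent from any
    species are dropped, since the cross-species comparison is undefined
    for them.
    """
    need = {"species", "source_gene_id", "reference_symbol"}
    if not need <= set(ortholog_map.columns):
        raise ValueError(f"ortholog map needs columns {sorted(need)}")
    dup = ortholog_map.duplicated(["species", "source_gene_id"], keep=False)
    amb = ortholog_map[dup].groupby(["species", "source_gene_id"])[
        "reference_symbol"].nunique()
    if (amb > 1).any():
        raise ValueError("ortholog map assigns multiple reference symbols to "
                         "one (species, gene) pair")
    if collision_rule not in ("sum", "mean"):
        raise ValueError(f"unknown collision rule {collision_rule!r}")

    species_present = sorted({species_of_sample[s] for s in matrix.columns})
    per_species: dict[str, pd.DataFrame] = {}
    coverage: dict[str, int] = {}
    for sp in species_present:
        cols = [s for s in matrix.columns if species_of_sample[s] == sp]
        sub = matrix[cols]
        mapping = (ortholog_map[ortholog_map["species"] == sp]
                   .set_index("source_gene_id")["reference_symbol"])
        sub = sub.loc[sub.index.intersection(mapping.index)]
        grouped = sub.groupby(sub.index.map(mapping))
        per_species[sp] = grouped.sum() if collision_rule == "sum" else grouped.mean()
        coverage[sp] = per_species[sp].shape[0]

    common = None
    for sp, df in per_species.items():
        common = set(df.index) if common is None else common & set(df.index)
    if not common:
        raise ValueError(
            "no reference symbol is covered in every species; per-species "
            f"coverage: {coverage}")
    symbols = sorted(common)
    out = pd.concat([per_species[sp].loc[symbols] for sp in species_present],
                    axis=1)
    if not require_all_species:
        union = sorted(set().union(*[set(df.index) for df in per_species.values()]))
        out = pd.concat([per_species[sp].reindex(union)
                         for sp in species_present], axis=1)
    return out[matrix.columns.intersection(out.columns)]


def monotone_scaling_filter(matrix: pd.DataFrame,
                            species_order_by_mass: list[str],
                            species_of_sample: dict[str, str],
                            per_replicate: bool = False) -> list:
    """Genes whose expression strictly decreases with increasing body mass.

    ``species_order_by_mass`` lists species smallest first; a gene is
    retained when its per-species replicate means are strictly
    decreasing along that order.  ``per_replicate`` additionally demands
    every replicate of a species exceed every replicate of the next
    (stricter; off by default).
    """
    cols_by_species = {}
    for sp in species_order_by_mass:
        cols = [s for s in matrix.columns if species_of_sample[s] == sp]
        if not cols:
            raise ValueError(f"species {sp!r} in the order has no samples")
        cols_by_species[sp] = cols
    means = pd.DataFrame(
        {sp: matrix[cols].mean(axis=1) for sp, cols in cols_by_species.items()})
    dec = np.all(np.diff(means[species_order_by_mass].values, axis=1) < 0, axis=1)
    if per_replicate:
        for a, b in zip(species_order_by_mass, species_order_by_mass[1:]):
            dec &= (matrix[cols_by_species[a]].min(axis=1).values
                    > matrix[cols_by_species[b]].max(axis=1).values)
    return list(matrix.index[dec])


def anova_bonferroni(matrix: pd.DataFrame, genes: list,
                     species_of_sample: dict[str, str],
                     threshold: float = 0.01,
                     log_transform: bool = True) -> pd.DataFrame:
    """Per-gene one-way ANOVA across species with Bonferroni adjustment.

    The Bonferroni family is the gene list passed in (the genes that
    survived the monotone filter, matching the screen's filter-then-test
    sequence).  Values are log2(x+1)-transformed by default, the usual
    variance stabilisation for expression data.  Returns a DataFrame
    with F, raw p, adjusted p and a pass flag at the adjusted threshold.
    """
    species = sorted({species_of_sample[s] for s in matrix.columns})
    groups_cols = {sp: [s for s in matrix.columns if species_of_sample[s] == sp]
                   for sp in species}
    counts = {sp: len(c) for sp, c in groups_cols.items()}
    if any(n < 2 for n in counts.values()):
        raise ValueError(
            "one-way ANOVA needs >= 2 replicates in every species; replicate "
            f"counts: {counts}")
    sub = matrix.loc[genes]
    vals = np.log2(sub + 1.0) if log_transform else sub
    f_stat = np.empty(len(genes))
    p_raw = np.empty(len(genes))
    arrays = [vals[groups_cols[sp]].to_numpy(dtype=float) for sp in species]
    for i in range(len(genes)):
        samples = [a[i] for a in arrays]
        if all(np.ptp(s) == 0 for s in samples) and np.ptp(
                np.concatenate(samples)) == 0:
            f_stat[i], p_raw[i] = 0.0, 1.0
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            f, p = stats.f_oneway(*samples)
        f_stat[i] = f if np.isfinite(f) else np.inf
        p_raw[i] = p if np.isfinite(p) else 0.0
    m = len(genes)
    p_adj = np.minimum(p_raw * m, 1.0)
    return pd.DataFrame({
        "F": f_stat, "p_raw": p_raw, "p_adj": p_adj,
        "pass": p_adj <= threshold,
    }, index=pd.Index(genes, name="gene"))


def pathway_filter(genes: list, sets: GeneSetCollection) -> pd.DataFrame:
    """Restrict genes to members of at least one provided set.

    Returns a DataFrame (gene, memberships) for the retained genes, with
    memberships as a comma-joined, sorted list of set names.
    """
    rows = []
    for g in genes:
        member = sorted(name for name, members in sets.items() if g in members)
        if member:
            rows.append((g, ",".join(member)))
    return pd.DataFrame(rows, columns=["gene", "memberships"]).set_index("gene")


def gene_set_enrichment(query: list, universe: list,
                        sets: GeneSetCollection) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    The upper-tail probability of observing at least the seen overlap
    when drawing ``len(query)`` genes from the universe; Bonferroni
    adjustment across sets.  (An offline replacement for web enrichment
    services, over user-supplied GMT collections.)
    """
    uni = set(universe)
    q = set(query)
    stray = q - uni
    if stray:
        raise ValueError(f"query genes not in universe: {sorted(stray)[:5]}")
    rows = []
    for name, members in sets.items():
        in_uni = members & uni
        overlap = len(in_uni & q)
        if len(in_uni) == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(in_uni),
                                         len(q)))
        rows.append((name, overlap, len(in_uni), len(uni), len(q), p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                      "universe_size", "query_size", "p"])
    out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    return out.set_index("set").sort_values("p")


def cluster_heatmap_order(matrix: pd.DataFrame,
                          genes: list | None = None,
                          metric: str = "euclidean",
                          method: str = "average"):
    """Row/column orderings and linkage trees for a clustered heatmap.

    Rows are z-scored before clustering; zero-variance rows are kept as
    all-zero and reported in the returned ``flat_rows`` list.  Returns a
    dict with z-scored values, row/column linkages and leaf orders;
    output is deterministic for a fixed input.
    """
    sub = matrix.loc[genes] if genes is not None else matrix
    if sub.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    vals = sub.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    flat = (sd[:, 0] == 0)
    sd[flat] = 1.0
    z = (vals - mu) / sd
    row_link = hierarchy.linkage(pdist(z, metric=metric), method=method)
    col_link = hierarchy.linkage(pdist(z.T, metric=metric), method=method)
    return {
        "z": pd.DataFrame(z, index=sub.index, columns=sub.columns),
        "row_linkage": row_link,
        "col_linkage": col_link,
        "row_order": [sub.index[i] for i in hierarchy.leaves_list(row_link)],
        "col_order": [sub.columns[i] for i in hierarchy.leaves_list(col_link)],
        "flat_rows": list(sub.index[flat]),
    }


def median_center_columns(matrix: pd.DataFrame, log_scale: bool = False,
                          ) -> pd.DataFrame:
    """Equalise per-sample medians (cross-species intensity normalisation).

    Each column is divided by its median (or reduced by it on log scale)
    so all column medians become 1 (0 on log scale).  Used for protein
    intensity tables before the monotone filter.
    """
    med = matrix.median(axis=0, skipna=True)
    if med.isna().any():
        bad = list(med.index[med.isna()])
        raise ValueError(f"all-missing column(s): {bad}")
    if log_scale:
        return matrix.sub(med, axis=1)
    if (med == 0).any():
        raise ValueError("zero median column; cannot scale")
    return matrix.div(med, axis=1)


# ---------------------------------------------------------------------------


class ScalingScreen:
    """Cross-species body-mass scaling screen as a fit-able model.

    Wires the normalisation, ortholog collapse, monotone filter, ANOVA/
    Bonferroni, pathway filter and enrichment steps into one object::

        res = ScalingScreen(cm, orthologs=om, gene_sets=gmt).fit(alpha=0.01)
        print(res.summary())

    Parameters
    ----------
    data : CountMatrix
        Raw counts (use ``kind="intensity"`` for already-continuous
        protein tables, which are median-centered instead of CPM/TMM
        normalised and skip ANOVA when replicates are single).
    orthologs : DataFrame, optional
        (species, source_gene_id, reference_symbol) records.  Omit when
        rows are already shared symbols.
    gene_sets : GeneSetCollection, optional
        Restricts results and drives the enrichment test.
    """

    def __init__(self, data: CountMatrix, orthologs: pd.DataFrame | None = None,
                 gene_sets: GeneSetCollection | None = None,
                 kind: str = "counts", use_tmm: bool = True,
                 collision_rule: str = "sum"):
        if kind not in ("counts", "intensity"):
            raise ValueError("kind must be 'counts' or 'intensity'")
        self.data = data
        self.orthologs = orthologs
        self.gene_sets = gene_sets
        self.kind = kind
        self.use_tmm = use_tmm
        self.collision_rule = collision_rule

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, samples: pd.DataFrame,
                       species: pd.DataFrame, **kwargs) -> "ScalingScreen":
        """Build from the TSV-shaped tables (see :mod:`fluxscale.io`)."""
        cm = CountMatrix(
            counts=counts,
            species_of_sample=dict(zip(samples["sample_id"], samples["species"])),
            body_mass_of_species=dict(zip(species["species"],
                                          species["body_mass_g"])),
        )
        return cls(cm, **kwargs)

    def fit(self, alpha: float = 0.01, run_anova: bool | None = None,
            ) -> "ScreenResults":
        cm = self.data
        sos = cm.species_of_sample
        norm_log: dict[str, pd.Series] = {}
        if self.kind == "counts":
            lib = cm.counts.sum(axis=0)
            factors = (tmm_factors(cm.counts) if self.use_tmm
                       else pd.Series(1.0, index=cm.counts.columns))
            matrix = normalize_cpm(cm.counts, tmm=factors if self.use_tmm else None)
            norm_log = {"library_size": lib, "tmm_factor": factors}
        else:
            matrix = median_center_columns(cm.counts)

        if self.orthologs is not None:
            matrix = collapse_orthologs(matrix, self.orthologs, sos,
                                        collision_rule=self.collision_rule)

        order = cm.species_order_by_mass
        monotone = monotone_scaling_filter(matrix, order, sos)

        if run_anova is None:
            run_anova = all(len(cm.replicates(sp)) >= 2 for sp in order)
        if run_anova:
            anova = anova_bonferroni(matrix, monotone, sos, threshold=alpha)
        else:  # single-replicate designs (e.g. proteomics): filter only
            anova = pd.DataFrame({"F": np.nan, "p_raw": np.nan, "p_adj": np.nan,
                                  "pass": True},
                                 index=pd.Index(monotone, name="gene"))

        table = pd.DataFrame(index=pd.Index(matrix.index, name="gene"))
        for sp in order:
            table[f"mean_{sp}"] = matrix[cm.replicates(sp)].mean(axis=1)
        table["monotone"] = table.index.isin(monotone)
        table = table.join(anova[["F", "p_raw", "p_adj"]])
        table["pass"] = table.index.isin(anova.index[anova["pass"]])

        memberships = None
        enrichment = None
        if self.gene_sets is not None:
            hits = list(table.index[table["pass"]])
            memberships = pathway_filter(hits, self.gene_sets)
            table["memberships"] = memberships["memberships"].reindex(table.index)
            if hits:
                enrichment = gene_set_enrichment(hits, list(matrix.index),
                                                 self.gene_sets)

        final = [g for g in table.index[table["pass"]]
                 if memberships is None or g in memberships.index]
        clustering = None
        if len(final) >= 2:
            clustering = cluster_heatmap_order(matrix, final)

        return ScreenResults(self, matrix=matrix, table=table, alpha=alpha,
                             monotone=monotone, enrichment=enrichment,
                             clustering=clustering, norm_log=norm_log)


@dataclass
class ScreenResults:
    """Fitted screen: per-gene table, enrichment and clustering order."""

    model: ScalingScreen
    matrix: pd.DataFrame
    table: pd.DataFrame
    alpha: float
    monotone: list
    enrichment: pd.DataFrame | None = None
    clustering: dict | None = None
    norm_log: dict = field(default_factory=dict)

    @property
    def passing_genes(self) -> list:
        return list(self.table.index[self.table["pass"]])

    def summary(self) -> str:
        cm = self.model.data
        order = cm.species_order_by_mass
        lines = [
            "Cross-species scaling screen",
            f"  species (smallest body mass first): {', '.join(order)}",
            f"  genes compared across all species:  {self.matrix.shape[0]}",
            f"  strictly mass-ordered (monotone):   {len(self.monotone)}",
            f"  significant at adjusted p <= {self.alpha:g}:  "
            f"{len(self.passing_genes)}",
        ]
        if self.enrichment is not None and len(self.enrichment):
            top = self.enrichment.iloc[0]
            lines.append(
                f"  top enriched set: {self.enrichment.index[0]} "
                f"(overlap {int(top['overlap'])}/{int(top['set_size'])}, "
                f"adjusted p = {top['p_adj']:.3g})")
        return "\n".join(lines)

    def plot_heatmap(self, ax=None):
        """Clustered z-score heatmap of the passing genes (needs matplotlib)."""
        if self.clustering is None:
            raise ValueError("no clustering available (fewer than 2 hits)")
        import matplotlib.pyplot as plt

        z = self.clustering["z"].loc[self.clustering["row_order"],
                                     self.clustering["col_order"]]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, max(2, 0.2 * len(z))))
        im = ax.imshow(z.values, aspect="auto", cmap="vlag"
                       if "vlag" in plt.colormaps() else "coolwarm")
        ax.set_xticks(range(z.shape[1]), z.columns, rotation=90)
        ax.set_yticks(range(z.shape[0]), z.index, fontsize=6)
        ax.figure.colorbar(im, ax=ax, label="row z-score")
        return ax
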
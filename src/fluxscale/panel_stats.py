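"""Two-species comparison and clustering of flux panels.

A flux panel is a samples x features table (EGP, V_PC, V_CS, V_PDH, FAO,
palmitate/NEFA turnover, ...) with a species label per sample.  The
analyses mirror the classic two-group workflow: per-feature two-tailed
unpaired Student's t-tests with fold differences of the group means, and
z-scored hierarchical clustering of samples with a species-purity score
of the two-cluster cut.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["two_group_test", "cluster_panel", "species_purity",
           "FluxPanelModel", "PanelResults"]


def two_group_test(values_a, values_b, equal_var: bool = True) -> dict:
    """Two-tailed unpaired t-test and fold difference of the means.

    Student's pooled-variance form by default (Welch via
    ``equal_var=False``).  Zero pooled variance: p = 1 when the means are
    equal, otherwise the comparison is degenerate and flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    fold = a.mean() / b.mean() if b.mean() != 0 else np.inf
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "p": 1.0, "fold": fold, "degenerate": False}
        return {"t": np.inf, "p": 0.0, "fold": fold, "degenerate": True}
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(t), "p": float(p), "fold": float(fold),
            "degenerate": False}


def cluster_panel(panel: pd.DataFrame, metric: str = "euclidean",
                  method: str = "average"):
    """Hierarchical clustering of samples on z-scored features.

    ``panel`` is numeric, samples x features.  Constant features carry no
    distance information and are dropped with a warning.  Returns a dict
    with the linkage matrix, deterministic leaf order and the z-scored
    values used.
    """
    if panel.shape[0] < 2:
        raise ValueError("need >= 2 samples to cluster")
    vals = panel.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"constant feature(s) dropped: "
                      f"{list(panel.columns[const])}", stacklevel=2)
        vals = vals[:, ~const]
        if vals.shape[1] == 0:
            raise ValueError("all features constant; nothing to cluster")
        sd = sd[~const]
    z = (vals - vals.mean(axis=0)) / sd
    link = hierarchy.linkage(pdist(z, metric=metric), method=method)
    return {
        "linkage": link,
        "leaf_order": [panel.index[i] for i in hierarchy.leaves_list(link)],
        "z": pd.DataFrame(z, index=panel.index,
                          columns=panel.columns[~const]),
    }


def species_purity(linkage: np.ndarray, labels, k: int = 2) -> float:
    """Majority-class purity of the k-cluster cut of a linkage tree.

    Purity = sum over clusters of the majority label count, divided by
    n; 1.0 for a perfect species split, ~the balanced-null expectation
    for uninformative panels.
    """
    labels = list(labels)
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    assign = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    total = 0
    for c in np.unique(assign):
        members = [labels[i] for i in range(n) if assign[i] == c]
        total += pd.Series(members).value_counts().iloc[0]
    return total / n


class FluxPanelModel:
    """Two-species flux-panel comparison (statsmodels-style model).

    ``panel`` has a ``species`` column and numeric flux features
    (optionally a ``sample_id`` column / index).  ``fit`` runs the
    per-feature Student's t-tests (species A vs B in the given or sorted
    label order), clusters the samples and scores species purity.
    """

    def __init__(self, panel: pd.DataFrame, species_order: list[str] | None = None,
                 equal_var: bool = True):
        if "species" not in panel.columns:
            raise ValueError("panel needs a 'species' column")
        panel = panel.copy()
        if "sample_id" in panel.columns:
            panel = panel.set_index("sample_id")
        self.species = panel["species"].astype(str)
        self.features = panel.drop(columns=["species"]).apply(
            pd.to_numeric, errors="raise")
        labels = species_order or sorted(self.species.unique())
        if len(labels) != 2:
            raise ValueError(f"exactly two species required, got {labels}")
        self.labels = labels
        self.equal_var = equal_var

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "FluxPanelModel":
        return cls(df, **kwargs)

    def fit(self, k: int = 2) -> "PanelResults":
        a_mask = self.species == self.labels[0]
        b_mask = self.species == self.labels[1]
        if a_mask.sum() < 2 or b_mask.sum() < 2:
            raise ValueError("need >= 2 samples per species for tests; got "
                             f"{int(a_mask.sum())} and {int(b_mask.sum())}")
        rows = {}
        for feat in self.features.columns:
            col = self.features[feat]
            if not np.isfinite(col).all():
                warnings.warn(f"feature {feat!r} has non-finite values; "
                              "excluded from tests", stacklevel=2)
                continue
            rows[feat] = two_group_test(col[a_mask], col[b_mask],
                                        equal_var=self.equal_var)
        tests = pd.DataFrame(rows).T
        clust = cluster_panel(self.features)
        purity = species_purity(clust["linkage"], list(self.species), k=k)
        return PanelResults(self, tests, clust, purity)


class PanelResults:
    def __init__(self, model: FluxPanelModel, tests: pd.DataFrame,
                 clustering: dict, purity: float):
        self.model = model
        self.tests = tests
        self.clustering = clustering
        self.purity = purity

    def summary(self) -> str:
        a, b = self.model.labels
        lines = [f"Flux panel: {a} vs {b} "
                 f"(n = {int((self.model.species == a).sum())} "
                 f"and {int((self.model.species == b).sum())})",
                 self.tests.to_string(float_format=lambda v: f"{v:.4g}"),
                 f"two-cluster species purity: {self.purity:.3f}"]
        return "\n".join(lines)

    def plot_dendrogram(self, ax=None):
        """Sample dendrogram coloured by species (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        hierarchy.dendrogram(self.clustering["linkage"],
                             labels=list(self.clustering["z"].index), ax=ax)
        ax.set_ylabel("distance")
        return ax
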
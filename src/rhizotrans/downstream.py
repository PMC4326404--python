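"""Downstream analysis: host-specificity calls, family aggregation,
control-relative expression and hierarchical clustering.

Host-specific genes are defined by set intersection: significantly
different between the two host co-cultures (maize vs tomato) *and*
significantly up-regulated versus the axenic fungal control in at least
one host interaction.  Which host a gene prefers is decided by the
direction of the maize-vs-tomato contrast (no extra fold cutoff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .differential import DEResults
from .io import SignalMatrix, ValidationError

__all__ = [
    "HostSpecificityCalls",
    "call_host_specificity",
    "aggregate_families",
    "relative_expression",
    "hierarchical_cluster",
    "ClusterResult",
]


# ---------------------------------------------------------------------------
# host specificity
# ---------------------------------------------------------------------------

@dataclass
class HostSpecificityCalls:
    """Per-gene host-specificity classification.

    ``table`` columns: ``in_MvsC_up, in_TvsC_up, in_MvsT`` (booleans),
    ``tomato_over_maize_ratio`` and ``class`` in {``shared_up``,
    ``maize_preferential``, ``tomato_preferential``,
    ``host_regulated_only``, ``none``}.
    """

    table: pd.DataFrame

    @property
    def host_specific(self) -> pd.Index:
        mask = self.table["class"].isin(["maize_preferential", "tomato_preferential"])
        return self.table.index[mask]

    @property
    def shared_up(self) -> pd.Index:
        return self.table.index[self.table["in_MvsC_up"] & self.table["in_TvsC_up"]]

    def counts(self) -> dict[str, int]:
        """Set sizes for the Venn layout: up on maize, up on tomato, shared,
        host-specific, and total modulated (union of the two up-sets)."""
        t = self.table
        up_m = int(t["in_MvsC_up"].sum())
        up_t = int(t["in_TvsC_up"].sum())
        shared = int((t["in_MvsC_up"] & t["in_TvsC_up"]).sum())
        return {
            "up_maize": up_m,
            "up_tomato": up_t,
            "shared_up": shared,
            "host_specific": int(len(self.host_specific)),
            "total_modulated": up_m + up_t - shared,
        }

    def summary(self) -> str:
        c = self.counts()
        cls = self.table["class"].value_counts()
        lines = ["Host-specificity calls", "=" * 40]
        lines += [f"{k:18s} {v}" for k, v in c.items()]
        lines += ["", "class breakdown:", cls.to_string()]
        return "\n".join(lines)


def call_host_specificity(
    de_mvsc: DEResults, de_tvsc: DEResults, de_mvst: DEResults,
) -> HostSpecificityCalls:
    """Classify genes by host response from the three pairwise contrasts.

    Parameters
    ----------
    de_mvsc, de_tvsc
        Maize-vs-control and tomato-vs-control results (first condition
        is the plant interaction, so ``t > 0`` means up on the plant).
    de_mvst
        Maize-vs-tomato result (``t > 0`` means higher on maize).

    The host-specific set is ``significant(MvsT) ∩ [up(MvsC) ∪ up(TvsC)]``.
    Within it, the sign of the MvsT contrast assigns ``maize_preferential``
    (higher on maize, tomato/maize ratio < 1) or ``tomato_preferential``.
    Genes up in both host interactions but not host-differential are
    ``shared_up``; significant in MvsT only, ``host_regulated_only``.
    """
    universes = [set(r.table.index) for r in (de_mvsc, de_tvsc, de_mvst)]
    if not (universes[0] == universes[1] == universes[2]):
        sym = (universes[0] ^ universes[1]) | (universes[0] ^ universes[2])
        raise ValidationError(
            f"contrast tables cover different gene universes; symmetric "
            f"difference (first 10): {sorted(sym)[:10]}"
        )
    idx = de_mvsc.table.index
    up_m = de_mvsc.table["significant"] & (de_mvsc.table["t"] > 0)
    up_t = de_tvsc.table["significant"] & (de_tvsc.table["t"] > 0)
    up_t = up_t.reindex(idx)
    mvst = de_mvst.table.reindex(idx)
    in_mvst = mvst["significant"]

    # tomato / maize abundance ratio from the MvsT log10 group means
    # (mean_A = maize, mean_B = tomato), consistent with the t direction
    ratio = np.power(10.0, mvst["mean_B"] - mvst["mean_A"])

    host_specific = in_mvst & (up_m | up_t)
    cls = pd.Series("none", index=idx, dtype=object)
    cls[up_m & up_t] = "shared_up"
    cls[in_mvst & ~(up_m | up_t)] = "host_regulated_only"
    cls[host_specific & (mvst["t"] > 0)] = "maize_preferential"
    cls[host_specific & (mvst["t"] < 0)] = "tomato_preferential"

    table = pd.DataFrame({
        "in_MvsC_up": up_m,
        "in_TvsC_up": up_t,
        "in_MvsT": in_mvst,
        "tomato_over_maize_ratio": ratio,
        "class": cls,
    }, index=idx)
    return HostSpecificityCalls(table)


# ---------------------------------------------------------------------------
# family aggregation
# ---------------------------------------------------------------------------

def aggregate_families(m: SignalMatrix, ann: pd.DataFrame) -> pd.DataFrame:
    """Sum mean signals of family members per condition, with combined SEM.

    For each family label (e.g. a glycoside-hydrolase family ``GH7``) and
    each condition: the summed per-member mean across replicate arrays,
    with per-member SEM = SD/sqrt(n) combined across members by the
    square-root of the sum of squares.  Single-member families keep their
    member's SEM.

    Returns a table indexed by family with columns
    ``<condition>_sum, <condition>_sem`` plus ``n_members``.
    """
    fam = ann.reindex(m.probe_ids)["family"]
    members = fam.dropna()
    if members.empty:
        raise ValidationError("no probes carry a family label")
    conditions = list(dict.fromkeys(m.conditions))
    rows = {}
    for family, probes in members.groupby(members).groups.items():
        rec: dict[str, float] = {"n_members": len(probes)}
        for cond in conditions:
            cols = m.samples_of(cond)
            block = m.values.loc[probes, cols]
            means = block.mean(axis=1)
            sems = block.std(axis=1, ddof=1) / np.sqrt(len(cols))
            rec[f"{cond}_sum"] = float(means.sum())
            rec[f"{cond}_sem"] = float(np.sqrt(np.sum(sems ** 2)))
        rows[family] = rec
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "family"
    out["n_members"] = out["n_members"].astype(int)
    return out


# ---------------------------------------------------------------------------
# control-relative expression and clustering
# ---------------------------------------------------------------------------

def relative_expression(m: SignalMatrix, control: str = "Tv") -> pd.DataFrame:
    """log10 of each signal divided by the gene's mean control signal.

    Control-condition columns are included (their values scatter around
    zero).  Genes whose control mean is zero are excluded with a warning.
    """
    ctrl_cols = m.samples_of(control)
    if not ctrl_cols:
        raise ValidationError(f"control condition {control!r} not present")
    ctrl_mean = m.values[ctrl_cols].mean(axis=1)
    bad = ctrl_mean <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} gene(s) with zero control mean excluded",
            stacklevel=2,
        )
    vals = m.values.loc[~bad]
    return np.log10(vals.div(ctrl_mean[~bad], axis=0))


@dataclass
class ClusterResult:
    """Agglomerative clustering of one axis of a log-ratio matrix."""

    axis: str                 # "genes" or "samples"
    linkage: np.ndarray       # scipy linkage matrix
    labels: list[str]         # item labels in input order
    leaf_order: list[str]     # labels in dendrogram leaf order

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_dist: float) -> str:
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        hierarchy.dendrogram(self.linkage, labels=self.labels, ax=ax,
                             leaf_rotation=90, leaf_font_size=6)
        ax.set_title(f"average-linkage clustering ({self.axis})")
        return ax


def hierarchical_cluster(
    ratios: pd.DataFrame, axis: str = "genes"
) -> ClusterResult | tuple[ClusterResult, ClusterResult]:
    """Average-linkage agglomerative clustering with Euclidean distance.

    ``ratios`` is a genes x samples matrix of control-relative log10
    ratios (see :func:`relative_expression`).  ``axis`` selects clustering
    of ``"genes"`` (rows), ``"samples"`` (columns) or ``"both"``.  Rows
    with non-finite values are excluded with a warning.  scipy's linkage
    on the observation order is deterministic; leaf order is the standard
    dendrogram order with ties resolved by input index.
    """
    if axis not in ("genes", "samples", "both"):
        raise ValueError(f"axis must be 'genes', 'samples' or 'both', got {axis!r}")
    finite = np.isfinite(ratios.to_numpy(dtype=float)).all(axis=1)
    if not finite.all():
        warnings.warn(
            f"{int((~finite).sum())} row(s) with non-finite values excluded",
            stacklevel=2,
        )
    ratios = ratios.loc[finite]

    def one(mat: pd.DataFrame, which: str) -> ClusterResult:
        if mat.shape[0] < 2:
            raise ValidationError(f"need >= 2 items to cluster on axis {which!r}")
        Z = hierarchy.linkage(mat.to_numpy(dtype=float), method="average",
                              metric="euclidean")
        labels = [str(x) for x in mat.index]
        leaves = hierarchy.leaves_list(Z)
        return ClusterResult(axis=which, linkage=Z, labels=labels,
                             leaf_order=[labels[i] for i in leaves])

    if axis == "genes":
        return one(ratios, "genes")
    if axis == "samples":
        return one(ratios.T, "samples")
    return one(ratios, "genes"), one(ratios.T, "samples")
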
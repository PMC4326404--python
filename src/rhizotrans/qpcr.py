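"""Efficiency-corrected relative quantification of qPCR data, and the
log-log power-law agreement fit between qPCR and microarray signals.

A dilution series with calibration-line slope ``s`` (magnitude, in cycles
per log10 dilution) implies a per-cycle amplification factor

    E = 10 ** (1 / s)

(s = 3.3219 is perfect doubling, E = 2).  Relative transcript abundance of
a gene of interest against the reference gene (beta-tubulin here) in one
sample is

    abundance = E_ref ** Ct_ref / E_goi ** Ct_goi,

with technical duplicates averaged on the Ct scale first and biological
replicates summarized (mean +/- SEM) per condition afterwards.  A pure
delta-Ct mode (all efficiencies forced to 2) is available as a toggle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PRIMER_ASSAYS",
    "REFERENCE_GENE",
    "efficiency_from_slope",
    "load_assays",
    "relative_abundance",
    "powerlaw_fit",
    "PowerLawFit",
]

#: default reference assay: beta-tubulin
REFERENCE_GENE = "88010"

#: efficiency below which an assay is flagged below-optimal
_EFFICIENCY_FLAG = 1.8

# The validation primer panel: gene id, consensus annotation, amplicon
# length (bp) and dilution-series calibration slope (magnitude).
_ASSAY_TSV = """\
gene_id	annotation	amplicon	slope
90504	Glycoside hydrolase family 7 protein	126	3.42
46158	Secreted short-chain dehydrogenase/reductase	178	3.84
86039	Secreted NAD-dependent epimerase/dehydratase	182	3.37
17705	Small secreted cysteine rich	144	3.44
19757	Class II hydrophobin	134	3.49
42536	Endoglucanase	141	3.69
51095	Polygalacturonase, glycoside hydrolase family 28	163	3.39
51211	Acetyl xylan esterase	175	3.87
54057	Secreted short-chain dehydrogenase/reductase	167	3.82
56652	Xylanase, glycoside hydrolase family 10	191	4.25
88010	Beta tubulin	108	3.36
"""


def efficiency_from_slope(slope: float) -> float:
    """Per-cycle amplification factor implied by a dilution-series slope.

    ``slope`` is the magnitude of the calibration-line slope (cycles per
    log10 dilution); must exceed 1 for a meaningful efficiency.
    """
    if not slope > 1:
        raise ValueError(f"slope must exceed 1, got {slope}")
    return 10.0 ** (1.0 / slope)


def load_assays(source: str | pd.DataFrame | None = None) -> pd.DataFrame:
    """Load a primer assay table and derive per-assay efficiencies.

    ``source`` is a path to a tab-delimited table with columns
    ``gene_id`` and ``slope`` (optionally ``annotation``, ``amplicon``),
    an equivalent DataFrame, or None for the built-in validation panel.
    Adds ``efficiency`` and a ``below_optimal`` flag (efficiency < 1.8).
    """
    if source is None:
        df = pd.read_csv(StringIO(_ASSAY_TSV), sep="\t", dtype={"gene_id": str})
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or "slope" not in df.columns:
        raise ValueError("assay table needs 'gene_id' and 'slope' columns")
    df["gene_id"] = df["gene_id"].astype(str)
    df = df.set_index("gene_id")
    df["efficiency"] = [efficiency_from_slope(s) for s in df["slope"]]
    df["below_optimal"] = df["efficiency"] < _EFFICIENCY_FLAG
    return df


#: the built-in validation primer panel with derived efficiencies
PRIMER_ASSAYS = load_assays()


def relative_abundance(
    ct: pd.DataFrame,
    assays: pd.DataFrame | None = None,
    reference: str = REFERENCE_GENE,
    efficiency_corrected: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference-normalized transcript abundance from Ct values.

    Parameters
    ----------
    ct
        Long-format table with columns ``gene_id, sample_id, condition,
        ct`` (one row per technical replicate well).
    assays
        Assay table from :func:`load_assays`; defaults to the built-in
        panel.
    reference
        Reference gene id (beta-tubulin by default).
    efficiency_corrected
        If False, all efficiencies are forced to 2 (pure delta-Ct).

    Returns
    -------
    (per_sample, per_condition)
        ``per_sample``: abundance per (gene, sample); ``per_condition``:
        mean, SEM and n of biological replicates per (gene, condition).
    """
    assays = PRIMER_ASSAYS if assays is None else assays
    required = {"gene_id", "sample_id", "condition", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ct = ct.copy()
    ct["gene_id"] = ct["gene_id"].astype(str)
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    unknown = set(ct["gene_id"]) - set(assays.index)
    if unknown:
        raise ValueError(f"genes without assay entry: {sorted(unknown)}")
    if reference not in set(ct["gene_id"]):
        raise ValueError(f"reference gene {reference!r} absent from Ct table")

    eff = assays["efficiency"].copy()
    if not efficiency_corrected:
        eff[:] = 2.0

    # technical duplicates averaged on the Ct scale
    mean_ct = (
        ct.groupby(["gene_id", "sample_id", "condition"], sort=False)["ct"]
        .mean().reset_index()
    )
    ref = mean_ct[mean_ct["gene_id"] == reference].set_index("sample_id")["ct"]
    goi = mean_ct[mean_ct["gene_id"] != reference]

    no_ref = sorted(set(goi["sample_id"]) - set(ref.index))
    if no_ref:
        warnings.warn(
            f"sample(s) without reference Ct excluded: {no_ref}", stacklevel=2,
        )
        goi = goi[~goi["sample_id"].isin(no_ref)]

    e_ref = float(eff[reference])
    rows = []
    for _, r in goi.iterrows():
        e_g = float(eff[r["gene_id"]])
        abundance = e_ref ** ref[r["sample_id"]] / e_g ** r["ct"]
        rows.append({
            "gene_id": r["gene_id"], "sample_id": r["sample_id"],
            "condition": r["condition"], "abundance": abundance,
        })
    per_sample = pd.DataFrame(rows)

    def sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    per_condition = (
        per_sample.groupby(["gene_id", "condition"], sort=False)["abundance"]
        .agg(mean="mean", sem=sem, n="count").reset_index()
    )
    return per_sample, per_condition


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of ``y = prefactor * x ** exponent`` on log10 scales."""

    exponent: float
    prefactor: float
    r_squared: float
    n: int

    @property
    def log_intercept(self) -> float:
        return float(np.log10(self.prefactor))

    def predict(self, x):
        return self.prefactor * np.asarray(x, dtype=float) ** self.exponent

    def summary(self) -> str:
        return (
            "Power-law fit (OLS on log10-log10)\n"
            "==================================\n"
            f"exponent   {self.exponent:.4g}\n"
            f"prefactor  {self.prefactor:.4g}\n"
            f"R^2        {self.r_squared:.4f}\n"
            f"n          {self.n}"
        )

    def plot(self, x, y, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        x = np.asarray(x, dtype=float)
        ax.loglog(x, y, "o", ms=4)
        grid = np.geomspace(np.min(x), np.max(x), 50)
        ax.loglog(grid, self.predict(grid), "-",
                  label=f"y = {self.prefactor:.3g} x^{self.exponent:.3g}, "
                        f"R$^2$={self.r_squared:.3f}")
        ax.set_xlabel("qPCR relative abundance")
        ax.set_ylabel("microarray signal")
        ax.legend()
        return ax


def powerlaw_fit(x, y) -> PowerLawFit:
    """Fit ``log10(y) ~ log10(x)`` by ordinary least squares.

    Non-positive pairs are excluded with a warning; at least 3 pairs must
    remain.  Returns the exponent (slope), the linear-scale prefactor
    (10**intercept) and the R^2 of the log-log fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} non-positive/non-finite pair(s) excluded",
            stacklevel=2,
        )
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 positive pairs for the fit, got {x.size}")
    res = stats.linregress(np.log10(x), np.log10(y))
    return PowerLawFit(
        exponent=float(res.slope),
        prefactor=float(10.0 ** res.intercept),
        r_squared=float(res.rvalue ** 2),
        n=int(x.size),
    )
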
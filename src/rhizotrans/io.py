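"""Data model and readers/writers for signal matrices and probe annotation.

Signals are stored on the linear scale throughout; log10 transforms are
explicit operations downstream, never implicit.  Sample conditions are
carried in a plain-text design table (``sample_id <tab> condition``) rather
than parsed out of sample names, since repository sample titles are
free-text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SignalMatrix",
    "ParseError",
    "ValidationError",
    "ANNOTATION_COLUMNS",
    "validate_annotation",
    "read_signal_matrix",
    "write_signal_matrix",
    "read_annotation",
    "write_annotation",
    "read_design",
    "duplicate_groups",
    "collapse_technical_replicates",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Input data violated a contract of the data model."""


#: canonical column order of a probe annotation table
ANNOTATION_COLUMNS = [
    "probe_id",
    "gene_id_v1",
    "gene_id_v2",
    "is_control",
    "is_spike",
    "spike_name",
    "spike_log_conc",
    "family",
]


@dataclass(frozen=True)
class SignalMatrix:
    """Probes x samples linear-scale signal matrix with sample conditions.

    Attributes
    ----------
    values
        DataFrame indexed by probe_id with one column per sample_id;
        non-negative, finite, linear-scale intensities.
    conditions
        Series mapping sample_id -> condition label (e.g. ``Tv``,
        ``M+Tv``, ``T+Tv``), aligned to the columns of ``values``.
    scale
        ``"raw"`` or ``"normalized"``.
    """

    values: pd.DataFrame
    conditions: pd.Series
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "normalized"):
            raise ValidationError(f"scale must be 'raw' or 'normalized', got {self.scale!r}")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite signal at probe {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative signal at probe {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        missing = [s for s in self.values.columns if s not in self.conditions.index]
        if missing:
            raise ValidationError(f"samples missing from design: {missing}")
        # align condition order to column order
        object.__setattr__(self, "conditions", self.conditions.loc[self.values.columns])

    # -- convenience accessors -------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition, in column order."""
        return [s for s in self.sample_ids if self.conditions[s] == condition]

    def condition_counts(self) -> dict[str, int]:
        return self.conditions.value_counts().to_dict()

    def require_replicates(self, min_n: int = 2) -> None:
        """Raise unless every condition present has at least ``min_n`` samples."""
        for cond, n in self.condition_counts().items():
            if n < min_n:
                raise ValidationError(
                    f"condition {cond!r} has {n} sample(s); at least {min_n} required"
                )

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "SignalMatrix":
        """Copy carrying new values (same samples/conditions)."""
        return SignalMatrix(values, self.conditions.copy(), scale or self.scale)

    def log10(self, floor: float = 0.0) -> pd.DataFrame:
        """Explicit log10 view; values are clipped below at ``10**floor`` only
        when floor > 0 callers want that, otherwise zeros raise downstream."""
        vals = self.values.to_numpy(dtype=float)
        if floor > 0:
            vals = np.maximum(vals, floor)
        with np.errstate(divide="ignore"):
            return pd.DataFrame(np.log10(vals), index=self.probe_ids, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check and normalize a probe annotation table.

    Enforces: spikes are controls and carry a log concentration; non-control
    probes carry a gene id; probe_ids unique.  Returns the table indexed by
    probe_id with the canonical columns (missing optional columns added as
    nulls).
    """
    ann = ann.copy()
    if "probe_id" in ann.columns:
        ann = ann.set_index("probe_id")
    ann.index = ann.index.astype(str)
    if ann.index.duplicated().any():
        dupes = ann.index[ann.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated probe_id in annotation: {dupes[:5]}")
    for col in ANNOTATION_COLUMNS[1:]:
        if col not in ann.columns:
            ann[col] = (False if col in ("is_control", "is_spike") else np.nan)
    ann["is_control"] = ann["is_control"].fillna(False).astype(bool)
    ann["is_spike"] = ann["is_spike"].fillna(False).astype(bool)

    spikes = ann[ann["is_spike"]]
    if (~spikes["is_control"]).any():
        raise ValidationError("spike probes must be flagged is_control")
    if spikes["spike_log_conc"].isna().any():
        bad = spikes.index[spikes["spike_log_conc"].isna()].tolist()
        raise ValidationError(f"spike probes missing spike_log_conc: {bad[:5]}")
    noncontrol = ann[~ann["is_control"]]
    no_gene = noncontrol["gene_id_v1"].isna() & noncontrol["gene_id_v2"].isna()
    if no_gene.any():
        raise ValidationError(
            f"non-control probes without gene id: {noncontrol.index[no_gene].tolist()[:5]}"
        )
    return ann[ANNOTATION_COLUMNS[1:]]


def gene_of(ann: pd.DataFrame) -> pd.Series:
    """Preferred gene id per probe (v1 id, falling back to v2)."""
    return ann["gene_id_v1"].fillna(ann["gene_id_v2"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv_matrix(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    cols = header.split("\t")
    if len(cols) < 2:
        raise ParseError(f"{path}, line 1: header must give probe_id plus >=1 sample column")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric signal at probe {row!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        loc = np.argwhere(df.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing signal at probe {df.index[loc[0]]!r}, "
            f"sample {df.columns[loc[1]]!r}"
        )
    return df


def _read_series_matrix(path: Path) -> tuple[pd.DataFrame, list[str]]:
    """Minimal reader for the GEO series-matrix text dialect.

    Metadata lines start with ``!``; the expression block sits between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.  Sample
    titles are taken from the ``!Sample_title`` line when present.
    """
    titles: list[str] = []
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if line.startswith("!"):
                if line.startswith("!Sample_title"):
                    titles = [t.strip().strip('"') for t in line.split("\t")[1:]]
                continue
            if in_table:
                table_lines.append(line)
    if not table_lines:
        raise ParseError(f"{path}: no series_matrix_table_begin/end block found")
    header = [c.strip().strip('"') for c in table_lines[0].split("\t")]
    if len(header) < 2:
        raise ParseError(f"{path}: table header has no sample columns")
    rows = []
    index = []
    for i, line in enumerate(table_lines[1:], start=2):
        parts = [c.strip().strip('"') for c in line.split("\t")]
        if len(parts) != len(header):
            raise ParseError(f"{path}: table row {i} has {len(parts)} fields, expected {len(header)}")
        index.append(parts[0])
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value in table row {i}: {exc}") from exc
    df = pd.DataFrame(rows, index=pd.Index(index, name=header[0]), columns=header[1:])
    if titles and len(titles) == df.shape[1]:
        df.columns = titles
    return df, titles


def read_design(path: str | Path) -> pd.Series:
    """Read a two-column ``sample_id <tab> condition`` design table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: design table needs sample_id and condition columns")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="condition")
    if s.index.duplicated().any():
        raise ValidationError(f"{path}: duplicated sample_id in design table")
    return s


def read_signal_matrix(
    path: str | Path,
    format: str = "tsv",
    design: pd.Series | Mapping[str, str] | str | Path | None = None,
    scale: str = "raw",
) -> SignalMatrix:
    """Read a signal matrix from a tab-delimited table or series-matrix file.

    Parameters
    ----------
    path
        Input file.
    format
        ``"tsv"`` (probe_id + one column per sample) or ``"series_matrix"``
        (the ``!``-prefixed GEO text dialect).
    design
        Sample -> condition mapping, a path to a design table, or None
        (conditions then default to the single label ``"unknown"``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = _read_tsv_matrix(path)
    elif format == "series_matrix":
        df, _ = _read_series_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    if design is None:
        cond = pd.Series("unknown", index=df.columns, name="condition")
    elif isinstance(design, (str, Path)):
        cond = read_design(design)
    elif isinstance(design, pd.Series):
        cond = design
    else:
        cond = pd.Series(dict(design), name="condition")
    return SignalMatrix(df, cond, scale=scale)


def write_signal_matrix(m: SignalMatrix, path: str | Path, float_format: str = "%.10g") -> None:
    m.values.to_csv(path, sep="\t", index_label="probe_id", float_format=float_format)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(
        path, sep="\t",
        dtype={"probe_id": str, "gene_id_v1": str, "gene_id_v2": str,
               "spike_name": str, "family": str},
    )
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# technical replicates
# ---------------------------------------------------------------------------

_DUP_SUFFIX = re.compile(r"\.r\d+$")


def duplicate_groups(probe_ids: Iterable[str]) -> dict[str, list[str]]:
    """Group probe ids that are technical replicates of the same spot.

    Replicate spots share a base probe id and carry a ``.r<k>`` suffix
    (``p123``, ``p123.r2`` ...).  Returns base id -> member probe ids for
    groups with more than one member, preserving input order.
    """
    groups: dict[str, list[str]] = {}
    for p in probe_ids:
        groups.setdefault(_DUP_SUFFIX.sub("", str(p)), []).append(str(p))
    return {base: members for base, members in groups.items() if len(members) > 1}


def collapse_technical_replicates(
    m: SignalMatrix, ann: pd.DataFrame, mode: str = "independent"
) -> SignalMatrix:
    """Handle duplicate technical-replicate probes of the same gene.

    ``independent`` (the default) leaves the matrix untouched: every array
    spot is carried through the analysis as its own observation.  ``mean``
    replaces each duplicate-probe group (identified by the ``.r<k>`` probe
    id suffix) by its per-sample arithmetic mean, kept under the base
    probe id.  Duplicate probes annotated with conflicting gene ids raise.
    """
    if mode not in ("independent", "mean"):
        raise ValueError(f"mode must be 'independent' or 'mean', got {mode!r}")
    if mode == "independent":
        return m
    missing = m.probe_ids.difference(ann.index)
    if len(missing):
        raise ValidationError(f"probes missing from annotation: {missing.tolist()[:5]}")
    gene = gene_of(ann.loc[m.probe_ids])
    groups = duplicate_groups(m.probe_ids)
    for base, members in groups.items():
        genes = {g for g in (gene.get(p) for p in members) if pd.notna(g)}
        if len(genes) > 1:
            raise ValidationError(
                f"duplicate probe group {base!r} ({members}) maps to multiple genes: "
                f"{sorted(map(str, genes))}"
            )
    base_of = {p: _DUP_SUFFIX.sub("", str(p)) for p in m.probe_ids}
    collapsed = m.values.groupby(m.probe_ids.map(base_of), sort=False).mean()
    # keep first-appearance order of base ids
    seen: list[str] = []
    for p in m.probe_ids:
        b = base_of[p]
        if b not in seen:
            seen.append(b)
    collapsed = collapsed.loc[seen]
    collapsed.index.name = "probe_id"
    return m.with_values(collapsed)
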
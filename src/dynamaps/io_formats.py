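"""Tabular input/output for organellar-map experiments.

All artifacts are UTF-8, tab-separated tables with a single header row.
Lines starting with ``#`` before the header carry provenance metadata
(tool version and the parameters used to produce the file) and are
skipped on read.

The quantification table dialect follows the MaxQuant ``proteinGroups``
convention: one row per protein group, columns ``Protein ID``,
``Gene name``, ``Mol. weight [Da]`` and one ``Intensity <map>_<fraction>``
column per subcellular fraction of each replicate map.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__

#: Differential-centrifugation gradient, in spin order.  The 1K pellet is
#: nuclear-enriched; 3K-80K are the post-nuclear membrane fractions; the
#: cytosol is the final supernatant.
GRADIENT_ORDER: tuple[str, ...] = ("1K", "3K", "6K", "12K", "24K", "80K", "Cytosol")

#: The five post-nuclear membrane fractions used by SILAC, LFQ5 and TMT maps.
POST_NUCLEAR_FRACTIONS: tuple[str, ...] = ("3K", "6K", "12K", "24K", "80K")

#: Canonical compartment label set (12 subcellular localizations).
COMPARTMENTS: tuple[str, ...] = (
    "plasma membrane",
    "mitochondrion",
    "ER",
    "ER-high-curvature",
    "ERGIC",
    "Golgi",
    "endosome",
    "lysosome",
    "peroxisome",
    "nuclear pore complex",
    "large protein complex",
    "actin-binding",
)

QUANT_METHODS = ("SILAC", "LFQ", "TMT")

_ID_COL = "Protein ID"
_GENE_COL = "Gene name"
_MW_COL = "Mol. weight [Da]"
_INTENSITY_RE = re.compile(r"^Intensity (?P<rep>[^_]+)_(?P<frac>.+)$")


class FormatError(ValueError):
    """Raised when an input table violates the documented dialect."""


@dataclass
class QuantTable:
    """A protein x fraction measurement matrix for one replicate map.

    ``data`` is indexed by protein ID and holds ``gene_name``,
    ``mol_weight`` plus one numeric column per fraction (NaN = missing).
    For SILAC maps the values are heavy/light ratios (reference/sample);
    for LFQ and TMT they are intensities.
    """

    data: pd.DataFrame
    fractions: list[str]
    replicate_id: str
    quant_method: str

    def __post_init__(self) -> None:
        if self.quant_method not in QUANT_METHODS:
            raise FormatError(f"unknown quantification method {self.quant_method!r}")
        if not self.data.index.is_unique:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein IDs: {dups}")
        bad_mw = self.data.index[~(self.data["mol_weight"] > 0)].tolist()
        if bad_mw:
            raise FormatError(f"non-positive molecular weight for: {bad_mw}")
        order = {f: i for i, f in enumerate(GRADIENT_ORDER)}
        unknown = [f for f in self.fractions if f not in order]
        if unknown:
            raise FormatError(f"fractions {unknown} not in gradient {GRADIENT_ORDER}")
        idx = [order[f] for f in self.fractions]
        if idx != sorted(idx):
            raise FormatError("fraction labels must follow the gradient order")

    @property
    def n_proteins(self) -> int:
        return len(self.data)

    @property
    def intensities(self) -> pd.DataFrame:
        """Fraction columns only, in gradient order."""
        return self.data[self.fractions]

    @property
    def gene_names(self) -> pd.Series:
        return self.data["gene_name"]

    @property
    def mol_weights(self) -> pd.Series:
        return self.data["mol_weight"]


@dataclass
class MarkerTable:
    """Curated marker proteins: identifier (gene name) -> compartment."""

    assignments: pd.Series  # index: identifier, values: compartment label
    label_set: tuple[str, ...] = COMPARTMENTS

    def __post_init__(self) -> None:
        ident = self.assignments.index
        lowered = ident.str.lower()
        conflicted = []
        for key, grp in self.assignments.groupby(lowered):
            if grp.nunique() > 1:
                conflicted.append(key)
        if conflicted:
            raise FormatError(
                f"markers assigned to more than one compartment: {conflicted}"
            )
        # collapse duplicate rows with identical assignment
        keep = ~lowered.duplicated()
        self.assignments = self.assignments[keep]
        unknown = sorted(set(self.assignments) - set(self.label_set))
        if unknown:
            raise FormatError(f"unknown compartment labels: {unknown}")

    def __len__(self) -> int:
        return len(self.assignments)

    @property
    def compartments(self) -> list[str]:
        return sorted(self.assignments.unique())

    def lookup(self) -> dict[str, str]:
        """Case-insensitive identifier -> compartment mapping."""
        return {k.lower(): v for k, v in self.assignments.items()}


def _provenance(params: dict | None = None) -> list[str]:
    lines = [f"# dynamaps {__version__}"]
    if params:
        kv = " ".join(f"{k}={v}" for k, v in params.items())
        lines.append(f"# {kv}")
    return lines


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_quant_table(
    path,
    quant_method: str = "LFQ",
    zero_is_missing: bool | None = None,
) -> QuantTable:
    """Parse a quantification TSV into a :class:`QuantTable`.

    Missing values may be encoded as empty cells or ``NaN``.  When
    ``zero_is_missing`` is true (the default for LFQ, matching the
    MaxQuant convention of writing 0 for absent proteins), intensities of
    exactly 0 are also read as missing.
    """
    if zero_is_missing is None:
        zero_is_missing = quant_method == "LFQ"
    raw = _read_tsv(path)
    for col in (_ID_COL, _MW_COL):
        if col not in raw.columns:
            raise FormatError(f"mandatory column {col!r} missing from {path}")
    icols = [c for c in raw.columns if _INTENSITY_RE.match(c)]
    if len(icols) < 2:
        raise FormatError(f"need >=2 'Intensity <map>_<fraction>' columns in {path}")
    reps = {_INTENSITY_RE.match(c)["rep"] for c in icols}
    if len(reps) != 1:
        raise FormatError(f"one replicate map per table; found maps {sorted(reps)}")
    replicate_id = reps.pop()
    fracs = [_INTENSITY_RE.match(c)["frac"] for c in icols]

    data = pd.DataFrame(index=pd.Index(raw[_ID_COL], name="protein_id"))
    data["gene_name"] = raw.get(_GENE_COL, pd.Series("", index=raw.index)).fillna("").values
    try:
        data["mol_weight"] = pd.to_numeric(raw[_MW_COL], errors="raise").values
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric molecular weight in {path}: {exc}") from exc
    for col, frac in zip(icols, fracs):
        try:
            vals = pd.to_numeric(raw[col], errors="raise").astype(float).values
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric intensity in column {col!r}: {exc}") from exc
        if np.nanmin(vals, initial=0.0) < 0:
            rows = data.index[np.asarray(vals) < 0].tolist()
            raise FormatError(f"negative intensity in column {col!r}, rows {rows}")
        if zero_is_missing:
            vals = np.where(vals == 0.0, np.nan, vals)
        data[frac] = vals
    # restore gradient order (input column order is not trusted)
    order = [f for f in GRADIENT_ORDER if f in fracs]
    extra = [f for f in fracs if f not in GRADIENT_ORDER]
    if extra:
        raise FormatError(f"fractions {extra} not in gradient {GRADIENT_ORDER}")
    data = data[["gene_name", "mol_weight", *order]]
    return QuantTable(data, list(order), replicate_id, quant_method)


def write_quant_table(table: QuantTable, path, params: dict | None = None) -> None:
    out = pd.DataFrame(
        {
            _ID_COL: table.data.index,
            _GENE_COL: table.gene_names.values,
            _MW_COL: table.mol_weights.values,
        }
    )
    for frac in table.fractions:
        out[f"Intensity {table.replicate_id}_{frac}"] = table.data[frac].values
    meta = {"quant_method": table.quant_method, "replicate": table.replicate_id}
    meta.update(params or {})
    _write_with_header(out, path, meta)


def _write_with_header(df: pd.DataFrame, path, params: dict | None = None) -> None:
    buf = io.StringIO()
    for line in _provenance(params):
        buf.write(line + "\n")
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_marker_table(path, label_set: tuple[str, ...] = COMPARTMENTS) -> MarkerTable:
    """Read a two-column ``identifier<TAB>compartment`` marker list."""
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise FormatError(f"marker table {path} needs two columns (identifier, compartment)")
    if len(raw) == 0:
        raise FormatError(f"marker table {path} is empty")
    ident, comp = raw.columns[:2]
    ser = pd.Series(raw[comp].values, index=pd.Index(raw[ident], name="identifier"))
    return MarkerTable(ser, label_set)


def write_marker_table(markers: MarkerTable, path) -> None:
    out = pd.DataFrame(
        {"identifier": markers.assignments.index, "compartment": markers.assignments.values}
    )
    _write_with_header(out, path)


def match_markers_across_species(
    markers: MarkerTable, table: QuantTable
) -> tuple[MarkerTable, int]:
    """Restrict a marker list to the genes present in a quantification table.

    Matching is by gene name, case-insensitively, so that marker sets
    curated in one species can annotate maps of another (e.g. human marker
    genes matched against mouse gene symbols).  Returns the matched subset
    and the number of matches; zero matches is reported, not an error.
    """
    genes = set(table.gene_names.str.lower())
    keep = markers.assignments.index.str.lower().isin(genes)
    matched = markers.assignments[keep]
    sub = MarkerTable(matched.copy(), markers.label_set) if len(matched) else MarkerTable(
        pd.Series(dtype=object, index=pd.Index([], name="identifier")), markers.label_set
    )
    return sub, len(matched)
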
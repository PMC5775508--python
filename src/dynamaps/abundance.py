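"""Quantitative cellular anatomy from whole-cell profiling data.

Absolute scaling uses the proteomic ruler: histones are stoichiometric
with DNA, so the summed histone MS signal corresponds to a known protein
mass per cell (approximately the genome's DNA mass).  Scaling the total
MS signal by that anchor yields total protein mass per cell, per-protein
mass and copy numbers, and (given a cellular protein concentration) cell
volume and molar concentrations.  Combined with compartment predictions,
this gives each organelle's share of total cell protein mass and its
internal composition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import QuantTable, _write_with_header

N_AVOGADRO = 6.02214076e23

#: DNA mass per diploid cell (g); the ruler's anchor constant.
DNA_MASS_HUMAN = 6.5e-12
DNA_MASS_MOUSE = 5.9e-12

#: Default cellular protein concentration (g/L) for volume estimation.
PROTEIN_CONC_DEFAULT = 200.0

#: Gene-name families recognized as histones.
HISTONE_PATTERN = re.compile(r"^(HIST\w*|H1([.-]?\d+)?|H2A\w*|H2B\w*|H3\w*|H4\w*)$", re.I)

POOL_CATEGORIES = (
    "mostly_nuclear",
    "mostly_cytosolic",
    "mostly_membrane",
    "nuclear_and_cytosolic",
    "mixed",
)


@dataclass
class CellAnatomy:
    """Per-protein absolute abundance plus the global scaling constants.

    ``table`` columns: ``gene_name``, ``mol_weight``, ``total_intensity``,
    ``protein_mass`` (g/cell), ``copies`` (per cell), ``concentration``
    (mol/L).
    """

    table: pd.DataFrame
    total_protein_mass: float  # g/cell
    cell_volume: float  # L
    dna_mass_per_cell: float
    protein_conc: float

    @property
    def protein_mass(self) -> pd.Series:
        return self.table["protein_mass"]

    @property
    def copies(self) -> pd.Series:
        return self.table["copies"]


def find_histones(table: QuantTable, histone_ids: list[str] | None = None) -> pd.Index:
    """Histone rows, by explicit ID list or by gene-family pattern."""
    if histone_ids is not None:
        ids = set(h.lower() for h in histone_ids)
        mask = table.data.index.str.lower().isin(ids) | table.gene_names.str.lower().isin(ids)
    else:
        mask = table.gene_names.fillna("").map(lambda g: bool(HISTONE_PATTERN.match(g)))
    return table.data.index[np.asarray(mask, dtype=bool)]


def proteomic_ruler(
    table: QuantTable,
    histone_ids: list[str] | None = None,
    dna_mass_per_cell: float = DNA_MASS_HUMAN,
    protein_conc: float = PROTEIN_CONC_DEFAULT,
) -> CellAnatomy:
    """Estimate copy numbers, masses and concentrations per cell.

    Summed intensities over all measured fractions enter the ruler:
    ``total_protein_mass = dna_mass * (sum of all intensities) / (sum of
    histone intensities)``; each protein receives its intensity share of
    that mass, converted to copies via its molecular weight.  The result
    is invariant to global intensity rescaling and linear in
    ``dna_mass_per_cell``.
    """
    totals = table.intensities.sum(axis=1, skipna=True)
    if not (totals.sum() > 0):
        raise ValueError("summed intensities must be positive")
    hist = find_histones(table, histone_ids)
    if len(hist) == 0:
        expect = histone_ids if histone_ids is not None else [HISTONE_PATTERN.pattern]
        raise ValueError(f"no histone rows found; expected identifiers/pattern: {expect}")
    histone_signal = float(totals.loc[hist].sum())
    if not histone_signal > 0:
        raise ValueError("histone intensities sum to zero")

    total_mass = dna_mass_per_cell * float(totals.sum()) / histone_signal
    share = totals / totals.sum()
    protein_mass = total_mass * share
    copies = protein_mass * N_AVOGADRO / table.mol_weights
    cell_volume = total_mass / protein_conc  # g / (g/L) = L
    concentration = copies / (N_AVOGADRO * cell_volume)

    out = pd.DataFrame(
        {
            "gene_name": table.gene_names,
            "mol_weight": table.mol_weights,
            "total_intensity": totals,
            "protein_mass": protein_mass,
            "copies": copies,
            "concentration": concentration,
        }
    )
    return CellAnatomy(out, total_mass, cell_volume, dna_mass_per_cell, protein_conc)


def pool_distribution(
    table: QuantTable,
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Nuclear / membrane / cytosolic pool split of each protein.

    The nuclear pool is the 1K fraction, the membrane pool the summed
    post-nuclear pellets (3K-80K), the cytosolic pool the final
    supernatant.  Fractions of the per-protein total define the split;
    thresholds assign a category: ``mostly_X`` when a pool holds >= 0.6,
    ``nuclear_and_cytosolic`` when both nuclear and cytosolic hold >= 0.3
    with membrane < 0.2, else ``mixed``.  All-zero rows are excluded.
    """
    th = {"mostly": 0.6, "dual": 0.3, "dual_membrane_max": 0.2}
    th.update(thresholds or {})
    needed = {"1K", "Cytosol"}
    if not needed.issubset(table.fractions):
        raise ValueError("pool analysis needs the 1K and Cytosol fractions")
    membrane_fracs = [f for f in table.fractions if f not in needed]
    nuc = table.data["1K"].fillna(0.0)
    mem = table.data[membrane_fracs].fillna(0.0).sum(axis=1)
    cyt = table.data["Cytosol"].fillna(0.0)
    total = nuc + mem + cyt
    keep = total > 0
    pools = pd.DataFrame(
        {
            "nuclear": nuc[keep] / total[keep],
            "membrane": mem[keep] / total[keep],
            "cytosolic": cyt[keep] / total[keep],
        }
    )
    cat = np.full(len(pools), "mixed", dtype=object)
    dual = (
        (pools["nuclear"] >= th["dual"])
        & (pools["cytosolic"] >= th["dual"])
        & (pools["membrane"] < th["dual_membrane_max"])
    )
    cat[dual.to_numpy()] = "nuclear_and_cytosolic"
    for col, label in (
        ("nuclear", "mostly_nuclear"),
        ("membrane", "mostly_membrane"),
        ("cytosolic", "mostly_cytosolic"),
    ):
        cat[(pools[col] >= th["mostly"]).to_numpy()] = label
    pools["pool_category"] = cat
    return pools


def organelle_composition(
    anatomy: CellAnatomy, classes: pd.DataFrame, top_n: int = 10
) -> tuple[pd.Series, dict[str, pd.DataFrame]]:
    """Organelle shares of total cell protein mass, and per-organelle top lists.

    ``classes`` must carry a ``predicted_compartment`` column indexed by
    protein ID.  Proteins without a prediction accumulate under
    ``unassigned`` so mass fractions sum to 1.  Within each organelle,
    protein shares are normalized to the organelle's mass and the
    ``top_n`` most abundant proteins are listed (ties broken by ID).
    """
    mass = anatomy.protein_mass
    comp = classes["predicted_compartment"].reindex(mass.index)
    comp = comp.fillna("unassigned")
    organelle_mass = mass.groupby(comp).sum()
    fractions = (organelle_mass / mass.sum()).sort_values(ascending=False)

    tops: dict[str, pd.DataFrame] = {}
    for organelle, grp_mass in mass.groupby(comp):
        if organelle == "unassigned":
            continue
        df = pd.DataFrame(
            {
                "gene_name": anatomy.table.loc[grp_mass.index, "gene_name"],
                "protein_mass": grp_mass,
                "share_of_organelle": grp_mass / grp_mass.sum() if grp_mass.sum() > 0 else 0.0,
            }
        )
        # descending mass, ties broken by protein ID
        df = df.iloc[np.lexsort((df.index.to_numpy(), -df["protein_mass"].to_numpy()))]
        tops[organelle] = df.head(top_n)
    return fractions, tops


def cumulative_abundance(anatomy: CellAnatomy) -> pd.DataFrame:
    """Cumulative mass-fraction curve over proteins ranked by mass."""
    if len(anatomy.table) == 0:
        raise ValueError("anatomy table is empty")
    mass = anatomy.protein_mass.sort_values(ascending=False)
    cum = mass.cumsum() / mass.sum()
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(mass) + 1),
            "protein_id": mass.index,
            "cumulative_mass_fraction": cum.to_numpy(),
        }
    ).set_index("rank")


def proteome_overlap(
    a: CellAnatomy, b: CellAnatomy, size_scale: float = 1.0
) -> tuple[float, float]:
    """Qualitative and mass-weighted overlap of two proteomes.

    Orthology is operationalized as identical gene name
    (case-insensitive).  Qualitative overlap is the fraction of A's genes
    also present in B.  Quantitative overlap scales A's per-gene masses
    by ``size_scale`` (ratio of cell sizes) and sums the min of scaled A
    and B masses over shared genes, relative to A's total scaled mass.
    """
    mass_a = a.protein_mass.groupby(a.table["gene_name"].str.lower()).sum()
    mass_a = mass_a[mass_a.index != ""]
    mass_b = b.protein_mass.groupby(b.table["gene_name"].str.lower()).sum()
    mass_b = mass_b[mass_b.index != ""]
    if len(mass_a) == 0:
        return float("nan"), float("nan")
    shared = mass_a.index.intersection(mass_b.index)
    qualitative = len(shared) / len(mass_a)
    scaled_a = mass_a * size_scale
    quantitative = float(
        np.minimum(scaled_a.loc[shared], mass_b.loc[shared]).sum() / scaled_a.sum()
    )
    return float(qualitative), quantitative


def write_anatomy(
    anatomy: CellAnatomy, path, pools: pd.DataFrame | None = None
) -> None:
    out = anatomy.table.reset_index().rename(
        columns={
            "protein_id": "Protein ID",
            "gene_name": "Gene name",
            "copies": "Copies per cell",
            "protein_mass": "Mass [g/cell]",
        }
    )
    out["Concentration [nM]"] = anatomy.table["concentration"].to_numpy() * 1e9
    out = out.drop(columns=["concentration"])
    if pools is not None:
        for col, name in (
            ("nuclear", "Pool nuclear"),
            ("membrane", "Pool membrane"),
            ("cytosolic", "Pool cytosol"),
            ("pool_category", "Pool category"),
        ):
            out[name] = pools[col].reindex(anatomy.table.index).to_numpy()
    params = {
        "dna_mass_per_cell": anatomy.dna_mass_per_cell,
        "protein_conc": anatomy.protein_conc,
        "total_protein_mass": anatomy.total_protein_mass,
        "cell_volume": anatomy.cell_volume,
    }
    _write_with_header(out, path, params)
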
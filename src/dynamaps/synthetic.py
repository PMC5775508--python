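"""Synthetic organellar-map experiments.

The generator emulates the structure of a differential-centrifugation
profiling experiment: each compartment has a fixed archetype profile
over the map fractions (its fingerprint of pelleting behavior), every
protein draws multiplicative log-normal quantification noise around its
compartment archetype, and intensities scale with a log-normally
distributed per-protein abundance.  Replicate maps share the protein
cohort (identity, abundance, molecular weight) and differ only in noise.
Translocations are injected by moving designated proteins onto a convex
combination of source and target archetypes in the treated condition.
Mock maps are additional control draws, used downstream for empirical
FDR control.

Noise scales per quantification strategy are calibration constants of
this generator, ordered LFQ > TMT > SILAC to reflect the relative
quantification precision of the three strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import COMPARTMENTS, GRADIENT_ORDER, MarkerTable, QuantTable

#: Per-strategy multiplicative noise scale (sd of log-intensity per fraction).
NOISE_SIGMA: dict[str, float] = {"SILAC": 0.08, "TMT": 0.12, "LFQ": 0.25}

#: Map-order fraction names by fraction count.  The nuclear-enriched 1K
#: pellet is the sixth data point; the cytosol supernatant the seventh.
_MAP_FRACTIONS: dict[int, tuple[str, ...]] = {
    5: ("3K", "6K", "12K", "24K", "80K"),
    6: ("3K", "6K", "12K", "24K", "80K", "1K"),
    7: ("3K", "6K", "12K", "24K", "80K", "1K", "Cytosol"),
}

#: Six-fraction archetypes (map order: 3K, 6K, 12K, 24K, 80K, 1K).  The
#: nuclear pore complex / large protein complex pair differs materially
#: only in the 3K and 1K fractions (nuclear-proximal sedimentation) and
#: is nearly identical on fractions 2-5, so most of its separation is
#: carried by the sixth (1K) data point.
ARCHETYPES_6: dict[str, tuple[float, ...]] = {
    "plasma membrane": (0.35, 0.25, 0.15, 0.10, 0.05, 0.10),
    "mitochondrion": (0.15, 0.45, 0.25, 0.08, 0.04, 0.03),
    "ER": (0.10, 0.20, 0.35, 0.20, 0.10, 0.05),
    "ER-high-curvature": (0.05, 0.10, 0.25, 0.35, 0.20, 0.05),
    "ERGIC": (0.06, 0.18, 0.26, 0.28, 0.16, 0.06),
    "Golgi": (0.08, 0.30, 0.30, 0.17, 0.10, 0.05),
    "endosome": (0.05, 0.12, 0.18, 0.30, 0.30, 0.05),
    "lysosome": (0.12, 0.35, 0.20, 0.13, 0.15, 0.05),
    "peroxisome": (0.20, 0.40, 0.18, 0.10, 0.07, 0.05),
    "nuclear pore complex": (0.30, 0.05, 0.05, 0.05, 0.05, 0.50),
    "large protein complex": (0.55, 0.06, 0.07, 0.06, 0.06, 0.20),
    "actin-binding": (0.05, 0.08, 0.10, 0.15, 0.52, 0.10),
}

#: The archetype pair separable only through the 1K (sixth) fraction.
FRACTION6_PAIR: tuple[str, str] = ("nuclear pore complex", "large protein complex")

#: Cytosolic share per compartment for seven-fraction (whole-cell) maps.
CYTOSOL_SHARE: dict[str, float] = {
    "plasma membrane": 0.05,
    "mitochondrion": 0.03,
    "ER": 0.03,
    "ER-high-curvature": 0.03,
    "ERGIC": 0.03,
    "Golgi": 0.03,
    "endosome": 0.05,
    "lysosome": 0.03,
    "peroxisome": 0.03,
    "nuclear pore complex": 0.05,
    "large protein complex": 0.45,
    "actin-binding": 0.35,
}

#: Histone pelleting behavior for seven-fraction maps (map order).
_HISTONE_ARCHETYPE_7 = (0.01, 0.01, 0.01, 0.01, 0.01, 0.85, 0.10)

_HISTONE_GENES = ("H2AC1", "H2BC1", "H31", "H41", "H1-1", "H2AC4", "H2BC3", "H32")


def default_archetypes(n_fractions: int) -> dict[str, np.ndarray]:
    """Frozen archetype set for 5-, 6- or 7-fraction maps (map order).

    Five-fraction archetypes are the six-fraction ones restricted to the
    post-nuclear fractions and renormalized; seven-fraction archetypes
    allocate a per-compartment cytosol share and rescale the rest.
    """
    if n_fractions not in (5, 6, 7):
        raise ValueError(f"n_fractions must be 5, 6 or 7, got {n_fractions}")
    out: dict[str, np.ndarray] = {}
    for comp, arch6 in ARCHETYPES_6.items():
        a = np.asarray(arch6, dtype=float)
        if n_fractions == 5:
            a = a[:5] / a[:5].sum()
        elif n_fractions == 7:
            c = CYTOSOL_SHARE[comp]
            a = np.concatenate([a * (1.0 - c), [c]])
        out[comp] = a
    return out


@dataclass
class MoverSpec:
    """Inject ``count`` translocating proteins from ``source`` whose
    treated-condition archetype is ``(1-lam)*source + lam*target``."""

    source: str
    target: str
    lam: float
    count: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"mixing coefficient must be in [0,1], got {self.lam}")


@dataclass
class SimulationSpec:
    """Full description of a synthetic experiment; the seed fixes everything."""

    n_fractions: int = 6
    quant_method: str = "LFQ"
    noise_sigma: float | None = None  # default: NOISE_SIGMA[quant_method]
    archetypes: dict[str, np.ndarray] | None = None  # default: default_archetypes
    n_per_compartment: int = 50
    n_replicates: int = 3
    movers: list[MoverSpec] = field(default_factory=list)
    marker_fraction: float = 0.5
    abundance_median: float = 1.0e7
    abundance_sigma: float = 1.5  # sd of ln(abundance)
    n_histones: int | None = None  # default: 8 for whole-cell (7-fraction) maps
    dropout_quantile: float = 0.0  # LFQ missingness; off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma is None:
            self.noise_sigma = NOISE_SIGMA[self.quant_method]
        if self.archetypes is None:
            self.archetypes = default_archetypes(self.n_fractions)
        for comp, a in self.archetypes.items():
            a = np.asarray(a, dtype=float)
            if len(a) != self.n_fractions or (a < 0).any() or abs(a.sum() - 1) > 1e-9:
                raise ValueError(f"invalid archetype for {comp!r}: must be a sum-1 "
                                 f"vector of length {self.n_fractions}")
            self.archetypes[comp] = a
        if self.n_histones is None:
            self.n_histones = 8 if self.n_fractions == 7 else 0

    @property
    def fraction_names(self) -> tuple[str, ...]:
        return _MAP_FRACTIONS[self.n_fractions]

    @property
    def compartments(self) -> list[str]:
        return list(self.archetypes)


def _cohort(spec: SimulationSpec) -> pd.DataFrame:
    """Deterministic protein cohort shared by all maps of one experiment."""
    rng = np.random.default_rng([spec.seed, 90001])
    rows = []
    i = 0
    for comp in spec.compartments:
        for _ in range(spec.n_per_compartment):
            i += 1
            rows.append((f"SIM{i:05d}", f"GENE{i:05d}", comp))
    cohort = pd.DataFrame(rows, columns=["protein_id", "gene_name", "compartment"])
    n = len(cohort)
    cohort["mol_weight"] = 5.0e4 * np.exp(rng.normal(0.0, 0.4, n))
    cohort["abundance"] = spec.abundance_median * np.exp(
        rng.normal(0.0, spec.abundance_sigma, n)
    )
    cohort["is_mover"] = False
    cohort["mover_target"] = ""
    cohort["mover_lambda"] = 0.0

    for mv in spec.movers:
        if mv.source not in spec.archetypes or mv.target not in spec.archetypes:
            raise ValueError(f"mover references unknown compartment: {mv}")
        pool = cohort.index[(cohort["compartment"] == mv.source) & ~cohort["is_mover"]]
        if mv.count > len(pool):
            raise ValueError(
                f"cannot place {mv.count} movers in {mv.source!r} "
                f"({len(pool)} proteins available)"
            )
        chosen = rng.choice(pool.to_numpy(), size=mv.count, replace=False)
        cohort.loc[chosen, "is_mover"] = True
        cohort.loc[chosen, "mover_target"] = mv.target
        cohort.loc[chosen, "mover_lambda"] = mv.lam

    # markers: a fixed fraction of each compartment's non-movers
    cohort["is_marker"] = False
    for comp in spec.compartments:
        pool = cohort.index[(cohort["compartment"] == comp) & ~cohort["is_mover"]]
        n_mark = int(round(spec.marker_fraction * spec.n_per_compartment))
        n_mark = min(n_mark, len(pool))
        chosen = rng.choice(pool.to_numpy(), size=n_mark, replace=False)
        cohort.loc[chosen, "is_marker"] = True

    for k, gene in enumerate(_HISTONE_GENES[: spec.n_histones]):
        rows_h = {
            "protein_id": f"HIST{k + 1:02d}",
            "gene_name": gene,
            "compartment": "histone",
            "mol_weight": 1.4e4,
            "abundance": spec.abundance_median * 30.0,
            "is_mover": False,
            "mover_target": "",
            "mover_lambda": 0.0,
            "is_marker": False,
        }
        cohort = pd.concat([cohort, pd.DataFrame([rows_h])], ignore_index=True)
    return cohort


def _histone_archetype(spec: SimulationSpec) -> np.ndarray:
    a = np.asarray(_HISTONE_ARCHETYPE_7, dtype=float)
    if spec.n_fractions == 7:
        return a
    a = a[: spec.n_fractions] if spec.n_fractions == 5 else a[:6]
    return a / a.sum()


def _true_archetype_matrix(spec: SimulationSpec, cohort: pd.DataFrame, treated: bool) -> np.ndarray:
    """Per-protein expected profile (movers shifted in the treated condition)."""
    arch = np.empty((len(cohort), spec.n_fractions))
    hist = _histone_archetype(spec)
    for i, row in enumerate(cohort.itertuples(index=False)):
        if row.compartment == "histone":
            a = hist
        else:
            a = spec.archetypes[row.compartment]
        if treated and row.is_mover:
            a = (1.0 - row.mover_lambda) * a + row.mover_lambda * spec.archetypes[row.mover_target]
        arch[i] = a
    return arch


_CONDITION_CODE = {"control": 0, "treated": 1, "mock": 2}


def simulate_map(
    spec: SimulationSpec, replicate: int = 0, condition: str = "control"
) -> tuple[QuantTable, pd.DataFrame]:
    """Draw one replicate map; returns the quantification table and truth.

    Profiles are ``renormalize(archetype * exp(eps))`` with
    ``eps ~ N(0, sigma^2)`` i.i.d. per fraction; intensities are the
    profile scaled by the protein's abundance.  SILAC tables store
    reference/sample ratios instead of intensities.  The map's noise
    stream is derived deterministically from the master seed, the
    condition and the replicate index.
    """
    if condition not in _CONDITION_CODE:
        raise ValueError(f"condition must be one of {sorted(_CONDITION_CODE)}")
    cohort = _cohort(spec)
    arch = _true_archetype_matrix(spec, cohort, treated=(condition == "treated"))
    rng = np.random.default_rng(
        [spec.seed, 1000 + _CONDITION_CODE[condition] * 100 + replicate]
    )
    eps = rng.normal(0.0, spec.noise_sigma, arch.shape)
    noisy = arch * np.exp(eps)
    profiles = noisy / noisy.sum(axis=1, keepdims=True)
    intensities = profiles * cohort["abundance"].to_numpy()[:, None]

    rep_id = {"control": "C", "treated": "T", "mock": "M"}[condition] + str(replicate + 1)
    data = pd.DataFrame(index=pd.Index(cohort["protein_id"], name="protein_id"))
    data["gene_name"] = cohort["gene_name"].to_numpy()
    data["mol_weight"] = cohort["mol_weight"].to_numpy()

    frac_order = [f for f in GRADIENT_ORDER if f in spec.fraction_names]
    map_pos = {f: j for j, f in enumerate(spec.fraction_names)}
    for f in frac_order:
        if spec.quant_method == "SILAC":
            data[f] = 1.0 / profiles[:, map_pos[f]]
        else:
            data[f] = intensities[:, map_pos[f]]

    if spec.dropout_quantile > 0.0 and spec.quant_method == "LFQ":
        block = data[frac_order].to_numpy()
        cut = np.quantile(block, spec.dropout_quantile)
        data[frac_order] = np.where(block < cut, np.nan, block)

    table = QuantTable(data, frac_order, rep_id, spec.quant_method)
    truth = cohort.drop(columns=["abundance"]).set_index("protein_id")
    return table, truth


@dataclass
class SimulatedExperiment:
    control: list[QuantTable]
    treated: list[QuantTable]
    mock: list[QuantTable]
    truth: pd.DataFrame


def simulate_experiment(spec: SimulationSpec, with_movers: bool = True) -> SimulatedExperiment:
    """Full comparative experiment: n control, n treated and 2n mock maps.

    Treated maps apply the spec's mover shifts (disabled with
    ``with_movers=False``, yielding a pure null experiment); mock maps
    are further control draws to be split into control-vs-control pairs
    for FDR estimation.  All noise streams derive from the master seed.
    """
    eff = spec if with_movers else replace(spec, movers=[])
    control, truth = [], None
    for r in range(spec.n_replicates):
        t, truth = simulate_map(eff, r, "control")
        control.append(t)
    treated = [simulate_map(eff, r, "treated")[0] for r in range(spec.n_replicates)]
    mock = [simulate_map(eff, r, "mock")[0] for r in range(2 * spec.n_replicates)]
    return SimulatedExperiment(control, treated, mock, truth)


def marker_table(truth: pd.DataFrame) -> MarkerTable:
    """Marker annotations (gene -> compartment) from a generator truth table."""
    sel = truth[truth["is_marker"]]
    ser = pd.Series(
        sel["compartment"].to_numpy(),
        index=pd.Index(sel["gene_name"], name="identifier"),
    )
    labels = tuple(sorted(set(COMPARTMENTS) | set(ser.unique())))
    return MarkerTable(ser, labels)
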
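"""Synthetic inputs: toy atomic complexes, simulated assays, reference constants.

Everything the pipeline consumes can be generated here at desk scale, so the
full analysis runs without downloading a deposited structure or raw plate
data.  Toy complexes exercise the SASA/interface stage with a controllable
edge-to-edge gap between two chains; simulated luminescence datasets are
drawn from the same binding models the fitting stage assumes, with
multiplicative noise; and a registry of reference constants records the
experimentally reported values (dissociation constants, calcium EC50s,
competitor IC50, Z-factor) used as ground truth for recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .binding import TitrationDataset, occupancy_quadratic, _four_pl
from .structure import AtomRecord, Structure

__all__ = [
    "ToyComplexSpec",
    "SimulationConfig",
    "PlateData",
    "ReferenceConstant",
    "make_toy_complex",
    "simulate_assay",
    "reference_constants",
    "lookup_constant",
]


# --------------------------------------------------------------------------
# toy complexes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyComplexSpec:
    """Two parallel synthetic chains with a tunable contact gap.

    ``inter_chain_gap`` is the edge-to-edge (surface) separation between the
    closest atoms of the two chains: 0 means van der Waals contact, large
    values isolate the chains completely.  Geometry is deterministic; the
    seed only controls the optional coordinate jitter.
    """

    residues_per_chain: int = 6
    atoms_per_residue: int = 3
    atom_radius: float = 1.7
    geometry: Literal["straight", "helical"] = "straight"
    spacing_factor: float = 2.2  # centre spacing in units of atom_radius
    inter_chain_gap: float = 0.0
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residues_per_chain < 1 or self.atoms_per_residue < 1:
            raise ValueError("chain dimensions must be >= 1")
        if self.atom_radius <= 0:
            raise ValueError("atom_radius must be > 0")
        if self.inter_chain_gap < 0:
            raise ValueError("inter_chain_gap must be >= 0")
        if self.spacing_factor * self.atom_radius < 2 * self.atom_radius - 1e-9:
            raise ValueError("spacing_factor implies overlapping atoms within a chain")
        if self.jitter < 0 or self.jitter >= 0.25 * self.atom_radius:
            if self.jitter != 0:
                raise ValueError("jitter must be small relative to atom_radius")


def _chain_coords(spec: ToyComplexSpec) -> np.ndarray:
    n = spec.residues_per_chain * spec.atoms_per_residue
    step = spec.spacing_factor * spec.atom_radius
    i = np.arange(n, dtype=float)
    if spec.geometry == "straight":
        coords = np.column_stack((i * step, np.zeros(n), np.zeros(n)))
    elif spec.geometry == "helical":
        # gentle helix: rise per atom = step, radius = 2 atom radii
        r = 2.0 * spec.atom_radius
        theta = i * 0.6
        coords = np.column_stack((i * step * 0.6, r * np.cos(theta), r * np.sin(theta)))
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    return coords


def make_toy_complex(spec: ToyComplexSpec) -> Structure:
    """Build a two-chain complex (chains A and B) from a spec.

    Chain B is the same backbone translated along +z so that the minimum
    surface separation between chains equals ``inter_chain_gap``.
    """
    base = _chain_coords(spec)
    rng = np.random.default_rng(spec.seed)
    if spec.jitter > 0:
        base = base + rng.normal(0.0, spec.jitter, base.shape)
    offset = 2.0 * spec.atom_radius + spec.inter_chain_gap
    atoms: list[AtomRecord] = []
    serial = 1
    for chain_id, dz in (("A", 0.0), ("B", offset)):
        for res in range(spec.residues_per_chain):
            for j in range(spec.atoms_per_residue):
                idx = res * spec.atoms_per_residue + j
                x, y, z = base[idx]
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        atom_name=f"C{j + 1}",
                        element="C",
                        alt_loc="",
                        chain_id=chain_id,
                        res_seq=res + 1,
                        insertion_code="",
                        res_name="ALA",
                        x=float(x),
                        y=float(y),
                        z=float(z + dz),
                        radius=spec.atom_radius,
                    )
                )
                serial += 1
    return Structure(atoms, source_id=f"toy[{spec.geometry}]")


# --------------------------------------------------------------------------
# simulated assays
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateData:
    """Positive/negative control wells for assay-quality statistics."""

    pos: np.ndarray
    neg: np.ndarray


@dataclass(frozen=True)
class SimulationConfig:
    """Declarative recipe for one simulated luminescence dataset.

    ``truth`` supplies the model parameters per kind:

    * ``titration``   — kd_nM; optional fixed_nM (default 100, the standard
      fixed-component concentration), gain_rlu_per_nM (1000), background_rlu
      (500).
    * ``dose_response`` / ``inhibition`` — midpoint_nM, hill (1.5 asc / 1.0
      desc); optional top_rlu, bottom_rlu.
    * ``plate`` — mu_pos, mu_neg; optional n_wells (24).

    Noise is multiplicative Gaussian with coefficient of variation
    ``noise_cv``, truncated at zero.  Replicate ``j`` draws from the
    substream seeded by (seed, j), so adding replicates never reshuffles
    existing ones.
    """

    kind: Literal["titration", "dose_response", "inhibition", "plate"]
    truth: dict
    grid_min_nM: float = 1.0
    grid_max_nM: float = 1e5
    grid_points: int = 12
    replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.grid_min_nM <= 0 or self.grid_max_nM <= self.grid_min_nM:
            raise ValueError("grid must be positive and increasing")
        if self.grid_points < 5:
            raise ValueError("need at least 5 grid points")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")

    def grid(self) -> np.ndarray:
        return np.geomspace(self.grid_min_nM, self.grid_max_nM, self.grid_points)


def _noisy(mean: np.ndarray, cv: float, seed: int, replicate: int) -> np.ndarray:
    rng = np.random.default_rng([seed, replicate])
    if cv == 0:
        return mean.copy()
    return np.maximum(mean * (1.0 + cv * rng.standard_normal(mean.shape)), 0.0)


def simulate_assay(config: SimulationConfig) -> TitrationDataset | PlateData:
    """Draw one dataset from the configured binding model plus noise."""
    t = dict(config.truth)
    if config.kind == "plate":
        n = int(t.get("n_wells", 24))
        pos = _noisy(np.full(n, float(t["mu_pos"])), config.noise_cv, config.seed, 0)
        neg = _noisy(np.full(n, float(t["mu_neg"])), config.noise_cv, config.seed, 1)
        return PlateData(pos=pos, neg=neg)

    x = config.grid()
    if config.kind == "titration":
        kd = float(t["kd_nM"])
        fixed = float(t.get("fixed_nM", 100.0))
        gain = float(t.get("gain_rlu_per_nM", 1000.0))
        background = float(t.get("background_rlu", 500.0))
        mean = background + gain * occupancy_quadratic(x, fixed, kd)
        ion, ion_mM = t.get("ion", "Ca"), float(t.get("ion_conc_mM", 5.0))
    elif config.kind in ("dose_response", "inhibition"):
        m = float(t["midpoint_nM"])
        default_h = 1.5 if config.kind == "dose_response" else 1.0
        h = float(t.get("hill", default_h))
        if config.kind == "inhibition":
            h = -abs(h)
        top = float(t.get("top_rlu", 8e4))
        bottom = float(t.get("bottom_rlu", 2e3))
        mean = _four_pl(np.log10(x), bottom, top, np.log10(m), h)
        ion, ion_mM = t.get("ion", "Ca"), float(t.get("ion_conc_mM", 5.0))
        fixed = float(t.get("fixed_nM", 0.0))
    else:
        raise ValueError(f"unknown simulation kind {config.kind!r}")

    rlu = np.column_stack(
        [_noisy(mean, config.noise_cv, config.seed, j) for j in range(config.replicates)]
    )
    return TitrationDataset(
        titrant=config.kind,
        concentrations_nM=x,
        rlu=rlu,
        fixed_conc_nM=fixed if config.kind == "titration" else 0.0,
        ion=ion,
        ion_conc_mM=ion_mM,
    )


# --------------------------------------------------------------------------
# reference constants
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceConstant:
    key: str
    value: float
    units: str
    context: str

    @property
    def value_nM(self) -> float:
        """Value converted to nM where the units are a concentration."""
        scale = {"nM": 1.0, "uM": 1e3, "mM": 1e6}.get(self.units)
        if scale is None:
            raise ValueError(f"{self.key}: units {self.units!r} are not a concentration")
        return self.value * scale


_REGISTRY: dict[str, ReferenceConstant] = {
    c.key: c
    for c in [
        ReferenceConstant(
            "kd_het.capn1.ca", 185.4, "nM",
            "CAPN1:CAPNS1 heterodimer dissociation constant, saturation "
            "titration against 100 nM fixed component, 5 mM Ca2+",
        ),
        ReferenceConstant(
            "kd_het.capn2.ca", 508.6, "nM",
            "CAPN2:CAPNS1 heterodimer dissociation constant, 5 mM Ca2+",
        ),
        ReferenceConstant(
            "kd_het.capn1.mg", 361.8, "nM",
            "CAPN1:CAPNS1 heterodimer dissociation constant, 5 mM Mg2+ "
            "replacing Ca2+",
        ),
        ReferenceConstant(
            "kd_het.capn2.mg", 1651.0, "nM",
            "CAPN2:CAPNS1 heterodimer dissociation constant, 5 mM Mg2+",
        ),
        ReferenceConstant(
            "kd_homo.capns1.ca", 634.7, "nM",
            "CAPNS1:CAPNS1 small-subunit homodimer dissociation constant, "
            "100 nM fixed component, 5 mM Ca2+ (reported 95% CI 606.2-665.1)",
        ),
        ReferenceConstant(
            "ec50.ca.capn1", 59.9, "uM",
            "half-maximal Ca2+ concentration supporting the CAPN1:CAPNS1 "
            "interaction, dose-response in 5 mM Mg2+",
        ),
        ReferenceConstant(
            "ec50.ca.capn2", 940.8, "uM",
            "half-maximal Ca2+ concentration supporting the CAPN2:CAPNS1 "
            "interaction",
        ),
        ReferenceConstant(
            "ic50.competitor", 463.3, "nM",
            "half-maximal inhibition of the CAPN2:CAPNS1 biosensor "
            "(25 nM CAPNS1, 250 nM CAPN2) by LgBiT-less CAPNS1 competitor",
        ),
        ReferenceConstant(
            "zfactor.reported", 0.75, "",
            "screening-window Z-factor of the optimised CAPN2:CAPNS1 "
            "biosensor control plates",
        ),
    ]
}


def reference_constants() -> dict[str, ReferenceConstant]:
    """The registry of reported assay constants, keyed by dotted id."""
    return dict(_REGISTRY)


def lookup_constant(key: str) -> ReferenceConstant:
    """Fetch one constant; unknown keys raise with the list of valid keys."""
    try:
        return _REGISTRY[key]
    except KeyError:
        raise KeyError(
            f"unknown constant {key!r}; available: {', '.join(sorted(_REGISTRY))}"
        ) from None
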
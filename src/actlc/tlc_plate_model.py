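"""Forward physical model of a developed radioTLC plate.

A 3 uL aliquot of an unpurified Ac-225 labeling reaction is spotted at the
origin of a silica plate and developed in 10% MeOH / 10 mM EDTA.  The
labeled vector stays at the origin (Rf 0.0-0.3); unbound Ac-225 and any
daughter radionuclides free in solution travel as EDTA complexes toward
the solvent front (Rf > 0.7).  During the 35-45 min run, daughters born
from decays at the origin are partially swept toward the middle and the
front of the plate.  After development the plate is dry: each grid
section evolves as an isolated decay system, and a phosphor-screen read
reports the fraction of the total per-decay signal found in the product
section -- the measured RCP.

The model exposes exactly these mechanisms: element-wise chelation of
spotted daughters, migration fractions for in-run births, per-emission-
class detection weights, and an instantaneous read at any time after
development.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .decay_chain import (
    DecayChainModel,
    Inventory,
    activities,
    asymptotic_activity_ratio,
    evolve,
)

__all__ = [
    "ChelatorProfile",
    "DevelopmentModel",
    "DetectionModel",
    "SampleComposition",
    "PlateState",
    "DOTA_PROFILE",
    "MACROPA_PROFILE",
    "equilibrium_daughters",
    "sample_at_equilibrium",
    "spot_and_develop",
    "read_rcp",
    "section_signals",
    "quantify_grid",
    "read_grid_counts",
]


def element_of(nuclide_name: str) -> str:
    """Chemical element symbol of a nuclide name like ``Bi-213``."""
    return nuclide_name.split("-")[0]


@dataclass(frozen=True)
class ChelatorProfile:
    """Which daughter elements the free ligand binds in the reaction solution.

    ``solution_chelation`` maps an element symbol to the fraction of that
    element's in-solution atoms bound by the ligand at spotting (bound
    atoms remain at the origin).  ``recoil_retention`` is the fraction of
    daughters born on the dry plate that stay in their birth section; at
    box-grid resolution recoil relocation is unobservable, so the default
    is 1.
    """

    name: str
    solution_chelation: Mapping[str, float] = field(default_factory=dict)
    recoil_retention: float = 1.0

    def __post_init__(self) -> None:
        for el, frac in self.solution_chelation.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"chelation fraction for {el} outside [0, 1]")
        if not 0.0 <= self.recoil_retention <= 1.0:
            raise ValueError("recoil_retention outside [0, 1]")


#: DOTA-family ligands chelate Bi and Pb in solution at 95 C but cannot
#: re-capture daughters created by decay on the plate.
DOTA_PROFILE = ChelatorProfile("DOTA", {"Bi": 1.0, "Pb": 1.0})
#: macropa does not retain the daughter elements in solution.
MACROPA_PROFILE = ChelatorProfile("macropa", {})


@dataclass(frozen=True)
class DevelopmentModel:
    """TLC development: run duration and where in-run daughters end up.

    ``migration_to_mid`` / ``migration_to_front`` are the fractions of
    daughters born in the origin section during the run that finish in
    sections 2 and 3 respectively.
    """

    duration_min: float = 40.0
    migration_to_mid: float = 0.05
    migration_to_front: float = 0.05

    def __post_init__(self) -> None:
        if self.migration_to_mid < 0 or self.migration_to_front < 0:
            raise ValueError("migration fractions must be non-negative")
        if self.migration_to_mid + self.migration_to_front > 1.0:
            raise ValueError("migration fractions sum above 1")
        if self.duration_min < 0:
            raise ValueError("duration must be non-negative")


@dataclass(frozen=True)
class DetectionModel:
    """Per-decay phosphor-screen weight for each emission class."""

    efficiency: Mapping[str, float]

    def __post_init__(self) -> None:
        if not any(w > 0 for w in self.efficiency.values()):
            raise ValueError("at least one emission class needs a nonzero weight")
        if any(w < 0 for w in self.efficiency.values()):
            raise ValueError("efficiencies must be non-negative")

    @classmethod
    def default(cls) -> "DetectionModel":
        # alpha and beta at unit weight; the gamma that accompanies some
        # decays adds a 0.1 contribution folded into its parent class
        return cls(
            {
                "alpha": 1.0,
                "beta": 1.0,
                "gamma-accompanied-alpha": 1.1,
                "gamma-accompanied-beta": 1.1,
            }
        )

    @classmethod
    def uniform(cls, weight: float = 1.0) -> "DetectionModel":
        return cls({c: weight for c in DetectionModel.default().efficiency})


@dataclass(frozen=True)
class SampleComposition:
    """Latent state of the spotted aliquot.

    ``bound_fraction`` is the true labeling fraction p (Ac-225 bound to the
    vector); ``daughter_state_at_spotting`` holds daughter atoms per unit
    Ac-225 atom present in the solution at spotting.
    """

    bound_fraction: float
    chelator: ChelatorProfile
    daughter_state_at_spotting: Inventory

    def __post_init__(self) -> None:
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction outside [0, 1]")


@dataclass
class PlateState:
    """Per-section inventories of a developed plate.

    Sections: S1 = origin / product box (Rf 0.0-0.3), S2 = mid,
    S3 = solvent front (Rf > 0.7).
    """

    sections: Tuple[Inventory, Inventory, Inventory]
    time_of_development_end_h: float = 0.0

    RF_RANGES = ((0.0, 0.3), (0.3, 0.7), (0.7, 1.0))


def equilibrium_daughters(chain: DecayChainModel, per_ac: float = 1.0) -> Inventory:
    """Daughter atom counts per ``per_ac`` Ac-225 atoms at secular equilibrium.

    The [225Ac]AcCl3 stock is aged, so each unstable daughter carries its
    asymptotic activity ratio to the parent: N_d = R_d * (lambda_Ac /
    lambda_d) * N_Ac.  Prompt members hold negligible inventory and the
    stable terminus is invisible to the screen; both are omitted.
    """
    lam_root = chain.nuclides[chain.root].decay_constant
    atoms: Dict[str, float] = {}
    for name in chain.unstable_daughters():
        if chain.is_prompt(name):
            continue
        lam = chain.nuclides[name].decay_constant
        atoms[name] = asymptotic_activity_ratio(chain, name) * lam_root / lam * per_ac
    return Inventory(atoms)


def sample_at_equilibrium(
    bound_fraction: float,
    chelator: ChelatorProfile,
    chain: DecayChainModel,
) -> SampleComposition:
    """Convenience constructor: aged stock, daughters at secular equilibrium."""
    return SampleComposition(
        bound_fraction=bound_fraction,
        chelator=chelator,
        daughter_state_at_spotting=equilibrium_daughters(chain),
    )


def spot_and_develop(
    sample: SampleComposition,
    dev: DevelopmentModel,
    chain: DecayChainModel,
    total_ac_atoms: float = 1.0,
) -> PlateState:
    """Spot the sample, run the plate, return the developed plate state.

    Placement at spotting: the bound fraction p of Ac-225 stays at the
    origin (S1) and the rest travels to the front (S3); each spotted
    daughter splits element-wise by the chelator's solution-chelation
    fraction (bound -> S1, free -> S3).  During the run an atom born from
    a decay in S1 relocates at birth to S1:S2:S3 with fractions
    (1 - m2 - m3 : m2 : m3); atoms born in S2 or S3 stay where they are
    born.  The coupled decay-transport system is linear with constant
    coefficients over the run, so it is solved exactly with a matrix
    exponential on the (nuclide, section) state space.
    """
    for name in sample.daughter_state_at_spotting.atoms:
        if name not in chain:
            raise KeyError(f"sample daughter {name} not in chain")
    p = sample.bound_fraction
    s1_atoms: Dict[str, float] = {chain.root: p * total_ac_atoms}
    s3_atoms: Dict[str, float] = {chain.root: (1.0 - p) * total_ac_atoms}
    for name, n_per_ac in sample.daughter_state_at_spotting.atoms.items():
        n = n_per_ac * total_ac_atoms
        bound = sample.chelator.solution_chelation.get(element_of(name), 0.0)
        if bound:
            s1_atoms[name] = s1_atoms.get(name, 0.0) + bound * n
        if bound < 1.0:
            s3_atoms[name] = s3_atoms.get(name, 0.0) + (1.0 - bound) * n

    tau_h = dev.duration_min / 60.0
    m2, m3 = dev.migration_to_mid, dev.migration_to_front
    route = ((1.0 - m2 - m3, m2, m3), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    names = [n for n in chain.topological_order() if not chain.is_prompt(n)]
    index = {(n, s): 3 * i + s for i, n in enumerate(names) for s in range(3)}
    M = np.zeros((3 * len(names), 3 * len(names)))
    for n in names:
        lam = chain.nuclides[n].decay_constant
        if lam == 0.0:
            continue
        for s in range(3):
            col = index[(n, s)]
            M[col, col] -= lam
            for daughter, branch in chain.effective_daughters(n):
                for s_to in range(3):
                    frac = route[s][s_to]
                    if frac:
                        M[index[(daughter, s_to)], col] += lam * branch * frac

    state = np.zeros(3 * len(names))
    for name, n0 in s1_atoms.items():
        state[index[(name, 0)]] += n0
    for name, n0 in s3_atoms.items():
        state[index[(name, 2)]] += n0
    final = expm(M * tau_h) @ state

    sections = []
    for s in range(3):
        atoms = {
            n: float(final[index[(n, s)]])
            for n in names
            if final[index[(n, s)]] > 0.0
        }
        sections.append(Inventory(atoms, tau_h))
    return PlateState(
        sections=tuple(sections), time_of_development_end_h=tau_h
    )


def _inventory_signal(
    chain: DecayChainModel, inv: Inventory, det: DetectionModel
) -> float:
    act = activities(chain, inv)
    signal = 0.0
    for name, a in act.items():
        if a <= 0.0:
            continue
        nuc = chain.nuclides[name]
        weight = sum(
            m.branching * det.efficiency.get(m.emission_class, 0.0)
            for m in nuc.modes
        )
        signal += a * weight
    return signal


def section_signals(
    plate: PlateState,
    t_after_dev_h: float,
    det: DetectionModel,
    chain: DecayChainModel,
) -> Tuple[float, float, float]:
    """Per-section phosphor signal at ``t_after_dev_h`` hours after the run.

    Each section evolves independently (dry plate, no transport); the
    2 min exposure is treated as an instantaneous read.
    """
    if t_after_dev_h < 0:
        raise ValueError("t_after_dev_h must be non-negative")
    out = []
    for inv in plate.sections:
        evolved = evolve(chain, inv, t_after_dev_h)
        out.append(_inventory_signal(chain, evolved, det))
    return tuple(out)  # type: ignore[return-value]


def read_rcp(
    plate: PlateState,
    t_after_dev_h: float,
    det: DetectionModel,
    chain: DecayChainModel,
) -> float:
    """Measured RCP: product-section signal over total plate signal."""
    s1, s2, s3 = section_signals(plate, t_after_dev_h, det, chain)
    total = s1 + s2 + s3
    if total <= 0.0:
        raise ValueError("plate produced zero total signal")
    return s1 / total


def quantify_grid(counts: Sequence[float], product_boxes: Sequence[int]) -> float:
    """RCP from box-grid counts: product-box counts over all counts.

    ``product_boxes`` indexes the boxes covering the product (Rf 0.0-0.3);
    multiple boxes are summed, matching collapse of a finer grid to a
    product / non-product split.
    """
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero counts")
    product = arr[list(product_boxes)].sum()
    return float(product / total)


GRID_COLUMNS = ["plate_id", "box_index", "rf_low", "rf_high", "counts", "is_product"]


def read_grid_counts(path, sep: Optional[str] = None) -> pd.DataFrame:
    """Read a delimited grid-count table and return RCP per plate.

    Required columns: ``plate_id, box_index, rf_low, rf_high, counts,
    is_product``.  Returns a frame with columns ``plate_id, rcp``.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in GRID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"grid-count file missing columns: {missing}")
    records = []
    for plate_id, grp in df.groupby("plate_id", sort=False):
        counts = grp["counts"].to_numpy(dtype=float)
        product = np.flatnonzero(grp["is_product"].to_numpy(dtype=int))
        records.append({"plate_id": plate_id, "rcp": quantify_grid(counts, product)})
    return pd.DataFrame.from_records(records)
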
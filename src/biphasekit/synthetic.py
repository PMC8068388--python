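"""Synthetic dose-response assays and coordinate trajectories.

The generators define the study conditions every other stage is tested
against:

* :func:`simulate_assay` emulates an overnight cell-culture drug incubation
  read out by sandwich ELISA for Aβ1-40 — 12 log-spaced concentrations from
  0.1 nM to 100 µM plus a DMSO vehicle (0 M), 3 replicates, 5 % proportional
  noise, and censor flags outside the assay's 6–125 pM linear window
  (flagged, never dropped).
* :func:`four_drug_panel` provides four labelled drugs whose true biphasic
  parameters reproduce the qualitative orderings seen for γ-secretase
  modulators (see the truth table below).
* :func:`simulate_trajectory` builds a pseudo-Cα ensemble with known
  per-residue fluctuation amplitudes, the ground truth for the mobility
  analytics.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .mechanism import MechanismParams, dose_response_curve
from .model import BiphasicParams, evaluate_biphasic
from .mobility import Trajectory

__all__ = [
    "AssayDesign",
    "simulate_assay",
    "four_drug_panel",
    "PANEL_TRUTHS",
    "simulate_trajectory",
    "PanelDrug",
]


@dataclass(frozen=True)
class AssayDesign:
    """Dose grid, replication, noise model and censoring window of one assay.

    The noise model is proportional (``noise_cv``, coefficient of
    variation) plus optional additive Gaussian (``noise_sd``, response
    units); the ELISA linear window is in the same units as the responses
    (pM for absolute Aβ1-40 readouts) and may be ``None`` to disable
    censor flagging.
    """

    conc_min: float = 1e-10        # 0.1 nM
    conc_max: float = 1e-4         # 100 uM
    n_concentrations: int = 12
    n_replicates: int = 3
    include_vehicle: bool = True
    noise_cv: float = 0.05
    noise_sd: float = 0.0
    elisa_window: tuple[float, float] | None = (6.0, 125.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.conc_min < self.conc_max):
            raise ValueError("need 0 < conc_min < conc_max")
        if self.n_concentrations < 3:
            raise ValueError("need at least 3 concentrations")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.noise_cv < 0 or self.noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.elisa_window is not None and self.elisa_window[0] >= self.elisa_window[1]:
            raise ValueError("elisa_window must be (low, high) with low < high")

    def dose_grid(self) -> np.ndarray:
        grid = np.geomspace(self.conc_min, self.conc_max, self.n_concentrations)
        if self.include_vehicle:
            grid = np.concatenate([[0.0], grid])
        return grid

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["elisa_window"] is not None:
            d["elisa_window"] = list(d["elisa_window"])
        return d


def _censor_flags(values: np.ndarray, window) -> np.ndarray:
    if window is None:
        return np.full(len(values), "within")
    low, high = window
    flags = np.full(len(values), "within", dtype=object)
    flags[values < low] = "below"
    flags[values > high] = "above"
    return flags.astype(str)


def simulate_assay(
    truth,
    design: AssayDesign,
    drug_id: str = "drug",
    substrate: float | None = None,
):
    """Simulate one dose-response dataset from a known ground truth.

    ``truth`` is either :class:`BiphasicParams` (responses in the truth's
    own units) or :class:`MechanismParams` with ``substrate`` (molar), in
    which case responses are % of the zero-dose velocity.  Noise is applied
    per well; rows whose *measured* response falls outside the ELISA linear
    window carry ``below``/``above`` censor flags.
    """
    from .fitting import DoseResponseDataset  # local import to avoid a cycle

    grid = design.dose_grid()
    if isinstance(truth, BiphasicParams):
        clean = evaluate_biphasic(truth, grid)
        units = "pM"
    elif isinstance(truth, MechanismParams):
        if substrate is None:
            raise ValueError("mechanism truth requires a substrate concentration")
        clean = dose_response_curve(truth, substrate, grid).responses
        units = "%"
    else:
        raise TypeError(f"unsupported truth type {type(truth).__name__}")

    rng = np.random.default_rng(design.seed)
    rows = []
    for rep in range(design.n_replicates):
        z = rng.standard_normal(len(grid))
        z2 = rng.standard_normal(len(grid))
        noisy = clean * (1.0 + design.noise_cv * z) + design.noise_sd * z2
        for c, r in zip(grid, noisy):
            rows.append({"conc_M": c, "response": r, "replicate": f"rep{rep + 1}"})
    df = pd.DataFrame(rows)
    df["censor"] = _censor_flags(df["response"].to_numpy(), design.elisa_window)
    return DoseResponseDataset(drug_id, df, response_units=units)


# ---------------------------------------------------------------------------
# four-drug panel
# ---------------------------------------------------------------------------

# True parameters chosen once to satisfy the qualitative orderings reported
# for these four drugs in SH-SY5Y cells: LY-411,575 has the lowest
# EC50/IC50, the highest Hill coefficients and the highest attainable
# activation; DAPT the highest EC50/IC50 with the lowest Hills and lowest
# maximal activation; semagacestat sits between them; avagacestat matches
# LY-411,575's midpoints but with lower Hill coefficients.  Every drug
# shares the same baseline (one batch of cells split four ways) and has a
# steeper inhibition than activation phase (q > p).  Units: pM Aβ1-40.
PANEL_TRUTHS: dict[str, BiphasicParams] = {
    "LY-411575": BiphasicParams(
        PA=30.0, MA=90.0, MI=4.0, log10_EC50=-9.0, log10_IC50=-7.5, p=1.6, q=2.4
    ),
    "avagacestat": BiphasicParams(
        PA=30.0, MA=66.0, MI=4.0, log10_EC50=-8.8, log10_IC50=-7.3, p=1.0, q=1.5
    ),
    "semagacestat": BiphasicParams(
        PA=30.0, MA=75.0, MI=4.0, log10_EC50=-7.8, log10_IC50=-6.3, p=1.3, q=2.0
    ),
    "DAPT": BiphasicParams(
        PA=30.0, MA=60.0, MI=4.0, log10_EC50=-7.0, log10_IC50=-5.5, p=1.0, q=1.6
    ),
}


class PanelDrug(NamedTuple):
    dataset: object          # DoseResponseDataset
    truth: BiphasicParams
    design: AssayDesign


def four_drug_panel(seed: int = 0, design: AssayDesign | None = None) -> dict[str, PanelDrug]:
    """Simulate the four-drug panel under one shared assay design.

    Per-drug noise seeds are derived deterministically from ``seed``; the
    embedded truth records make the inter-drug orderings assertable.
    """
    base = design or AssayDesign()
    children = np.random.SeedSequence(seed).spawn(len(PANEL_TRUTHS))
    out = {}
    for (name, truth), child in zip(PANEL_TRUTHS.items(), children):
        kw = base.to_dict()
        if kw["elisa_window"] is not None:
            kw["elisa_window"] = tuple(kw["elisa_window"])
        kw["seed"] = int(child.generate_state(1)[0] % 2**31)
        d = AssayDesign(**kw)
        out[name] = PanelDrug(simulate_assay(truth, d, drug_id=name), truth, d)
    return out


def write_panel(panel: dict[str, PanelDrug], outdir) -> list[str]:
    """Write each panel dataset as CSV with a JSON truth/design sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, item in panel.items():
        csv = outdir / f"{name}.csv"
        item.dataset.to_csv(csv)
        sidecar = outdir / f"{name}.truth.json"
        sidecar.write_text(
            json.dumps(
                {"drug": name, "truth": item.truth.to_dict(), "design": item.design.to_dict()},
                indent=2,
            )
            + "\n"
        )
        written += [str(csv), str(sidecar)]
    return written


# ---------------------------------------------------------------------------
# trajectory fixture
# ---------------------------------------------------------------------------

def simulate_trajectory(
    n_residues: int,
    n_frames: int,
    amplitude_profile,
    rigid_motion: bool = False,
    seed: int = 0,
) -> Trajectory:
    """Pseudo-Cα ensemble with known per-residue fluctuation amplitudes.

    One CA atom per residue is placed on a smooth helical backbone; each
    frame displaces residue i by an isotropic Gaussian with per-coordinate
    standard deviation σ_i (Å), so the expected RMSF is σ_i·√3.  With
    ``rigid_motion`` every frame additionally receives a random global
    rotation and translation, which superposition must remove.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    sigma = np.broadcast_to(np.asarray(amplitude_profile, dtype=float), (n_residues,)).copy()
    if np.any(sigma < 0):
        raise ValueError("amplitude profile must be non-negative")
    rng = np.random.default_rng(seed)

    i = np.arange(n_residues)
    base = np.stack(
        [10.0 * np.cos(0.6 * i), 10.0 * np.sin(0.6 * i), 1.5 * i], axis=1
    )
    coords = base[None, :, :] + sigma[None, :, None] * rng.standard_normal(
        (n_frames, n_residues, 3)
    )
    if rigid_motion:
        for f in range(n_frames):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-20.0, 20.0, size=3)
            coords[f] = coords[f] @ R.T + t

    return Trajectory(
        coords=coords,
        res_ids=np.arange(1, n_residues + 1),
        res_names=np.full(n_residues, "ALA"),
        atom_names=np.full(n_residues, "CA"),
        chain_ids=np.full(n_residues, "A"),
    )
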
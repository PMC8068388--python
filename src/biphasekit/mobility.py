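"""Trajectory mobility analytics: superposition, RMSD, RMSF, PCA, ΔRMSF
and salt-bridge occupancy for coordinate ensembles.

Operates on desk-scale ensembles (multi-model PDB or XYZ, Å units): the
kind of per-residue mobility analysis used to locate flexible loops, rank
collective motions, and quantify how ligand binding damps them.  The
default analysis selection is Cα atoms; superposition uses a once-iterated
mean reference structure, standard essential-dynamics practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io
from scipy.spatial.distance import cdist

__all__ = [
    "Trajectory",
    "MobilityProfile",
    "PCAResult",
    "read_trajectory",
    "write_trajectory",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_profile",
    "pca_modes",
    "classify_mobility",
    "delta_rmsf",
    "salt_bridge_occupancy",
]

MOBILITY_CLASSES = np.array(["low", "intermediate", "high", "highest"])

#: side-chain atoms defining salt-bridge donors/acceptors
_ACIDIC = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_BASIC = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")}


@dataclass
class Trajectory:
    """A coordinate ensemble: frames × atoms × 3 (Å) with atom metadata."""

    coords: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    chain_ids: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError(f"coords must have shape (frames, atoms, 3), got {c.shape}")
        if c.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates must be finite")
        n = c.shape[1]
        for name in ("res_ids", "res_names", "atom_names", "chain_ids"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per atom")
            object.__setattr__(self, name, arr)
        self.coords = c

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, selection: str | np.ndarray | None = "CA") -> np.ndarray:
        """Atom indices for a selection: atom name (default "CA"), an index
        array/boolean mask, or None for all atoms."""
        if selection is None:
            return np.arange(self.n_atoms)
        if isinstance(selection, str):
            idx = np.flatnonzero(self.atom_names == selection)
        else:
            sel = np.asarray(selection)
            idx = np.flatnonzero(sel) if sel.dtype == bool else sel.astype(int)
        if len(idx) == 0:
            raise ValueError(f"selection {selection!r} matches no atoms")
        return idx


@dataclass
class MobilityProfile:
    """Per-residue RMSF (Å) with quartile mobility classes."""

    res_ids: np.ndarray
    rmsf: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.rmsf) < 0):
            raise ValueError("RMSF values must be non-negative")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"res_id": self.res_ids, "rmsf_A": self.rmsf, "mobility_class": self.classes}
        )


@dataclass
class PCAResult:
    """Essential-dynamics decomposition of the positional covariance."""

    eigenvalues: np.ndarray          # all, descending, Å²
    modes: np.ndarray                # (3N, k), orthonormal columns
    residue_amplitudes: np.ndarray   # (n_selected_atoms, k), per-mode norms
    res_ids: np.ndarray


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _traj_to_stack(traj: Trajectory) -> struc.AtomArrayStack:
    n = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord = traj.coords.astype(np.float32)
    stack.res_id = traj.res_ids.astype(int)
    stack.res_name = traj.res_names.astype("U5")
    stack.atom_name = traj.atom_names.astype("U6")
    stack.chain_id = traj.chain_ids.astype("U4")
    stack.set_annotation("element", np.array([a[0] for a in traj.atom_names], dtype="U2"))
    stack.set_annotation("hetero", np.zeros(n, dtype=bool))
    return stack


def write_trajectory(traj: Trajectory, path) -> None:
    """Write as a multi-model PDB (one MODEL record per frame).

    PDB coordinates carry 3 decimals, so values are quantized to 0.001 Å on
    disk; write→read→write is byte-stable.
    """
    f = pdb_io.PDBFile()
    f.set_structure(_traj_to_stack(traj))
    f.write(str(path))


def _from_stack(stack: struc.AtomArrayStack) -> Trajectory:
    return Trajectory(
        coords=np.asarray(stack.coord, dtype=float),
        res_ids=np.asarray(stack.res_id),
        res_names=np.asarray(stack.res_name),
        atom_names=np.asarray(stack.atom_name),
        chain_ids=np.asarray(stack.chain_id),
    )


def _read_xyz(path) -> Trajectory:
    """Plain XYZ trajectory: repeated blocks of (n_atoms, comment, atom rows).

    XYZ carries no residue topology; each atom becomes its own pseudo
    residue (res_id = atom index, residue name UNK, chain A).
    """
    frames = []
    names = None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame starting at line {i + 1}")
        frame_names, xyz = [], []
        for ln in block:
            parts = ln.split()
            frame_names.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        if names is None:
            names = frame_names
        elif frame_names != names:
            raise ValueError(f"{path}: inconsistent atom order between frames")
        frames.append(xyz)
        i += 2 + n
    coords = np.asarray(frames, dtype=float)
    n = coords.shape[1]
    return Trajectory(
        coords=coords,
        res_ids=np.arange(1, n + 1),
        res_names=np.full(n, "UNK"),
        atom_names=np.asarray(names),
        chain_ids=np.full(n, "A"),
    )


def read_trajectory(path, fmt: str | None = None) -> Trajectory:
    """Read a multi-model PDB or XYZ file into a :class:`Trajectory`.

    ``fmt`` is inferred from the extension when not given.  Files with a
    single model/frame are rejected (a trajectory needs >= 2 frames), as
    are files with inconsistent atom counts between frames.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt != "pdb":
        raise ValueError(f"unknown trajectory format {fmt!r}")
    f = pdb_io.PDBFile.read(str(path))
    try:
        stack = f.get_structure(model=None)
    except Exception as exc:
        raise ValueError(f"{path}: inconsistent models ({exc})") from exc
    if isinstance(stack, struc.AtomArray) or stack.stack_depth() < 2:
        raise ValueError(f"{path}: a trajectory needs >= 2 MODEL records")
    return _from_stack(stack)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray, weights=None):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with
    ``mobile @ rotation.T + translation ≈ reference``; the rotation is
    proper orthogonal (det = +1) and the RMSD is the minimum over all rigid
    transforms.  Degenerate point sets (all points collinear or coincident,
    which leave the rotation underdetermined) raise ``ValueError``.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n_points, 3)")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    cm = w @ mob
    cr = w @ ref
    m0 = mob - cm
    r0 = ref - cr
    H = (m0 * w[:, None]).T @ r0
    U, s, Vt = np.linalg.svd(H)
    spread = np.sqrt((w * (m0**2).sum(axis=1)).sum())
    if s[1] <= max(s[0], 1e-300) * 1e-9 or spread < 1e-12:
        raise ValueError("degenerate (collinear or coincident) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cr - R @ cm
    diff = m0 @ R.T - r0
    rmsd = float(np.sqrt((w * (diff**2).sum(axis=1)).sum()))
    return R, t, rmsd


def _superpose_frames(traj: Trajectory, sel: np.ndarray) -> np.ndarray:
    """All frames rigidly aligned on the selection to a once-iterated mean
    reference; the fitted transform is applied to every atom."""
    coords = traj.coords
    ref = coords[0, sel]
    aligned = np.empty_like(coords)
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(coords[f, sel], ref)
        aligned[f] = coords[f] @ R.T + t
    mean = aligned[:, sel].mean(axis=0)
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(coords[f, sel], mean)
        aligned[f] = coords[f] @ R.T + t
    return aligned


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def rmsd_series(traj: Trajectory, reference_frame: int = 0, selection="CA") -> np.ndarray:
    """Per-frame RMSD (Å) to a reference frame, after superposing each
    frame onto the reference on the analysis selection."""
    sel = traj.select(selection)
    ref = traj.coords[reference_frame, sel]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = kabsch_superpose(traj.coords[f, sel], ref)
    return out


def rmsf_profile(traj: Trajectory, selection="CA") -> MobilityProfile:
    """Per-residue RMSF about the mean structure (Å).

    RMSF_i = sqrt(mean_frames |r_i - <r_i>|²) after superposition to the
    once-iterated mean structure on the selection; mobility classes are
    RMSF quartiles (see :func:`classify_mobility`).
    """
    sel = traj.select(selection)
    aligned = _superpose_frames(traj, sel)[:, sel]
    mean = aligned.mean(axis=0)
    rmsf = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))
    res_ids = traj.res_ids[sel]
    return MobilityProfile(res_ids, rmsf, classify_mobility(rmsf))


def pca_modes(traj: Trajectory, selection="CA", k: int | None = None) -> PCAResult:
    """Essential dynamics: eigendecomposition of the 3N positional
    covariance after superposition.

    Eigenvalues are non-negative, descending, and sum to the total
    positional variance (mean squared deviation from the mean structure).
    ``k`` (default min(10, 3N)) limits the returned mode vectors only.
    """
    sel = traj.select(selection)
    three_n = 3 * len(sel)
    if k is None:
        k = min(10, three_n)
    if k > three_n:
        raise ValueError(f"k={k} exceeds 3N={three_n}")
    aligned = _superpose_frames(traj, sel)[:, sel]
    X = aligned.reshape(traj.n_frames, three_n)
    X = X - X.mean(axis=0)
    # SVD of the centered data: eigenvalues of the population covariance
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / traj.n_frames
    modes = Vt[:k].T
    amps = np.sqrt((modes.reshape(len(sel), 3, k) ** 2).sum(axis=1))
    return PCAResult(eigvals, modes, amps, traj.res_ids[sel])


def classify_mobility(rmsf: np.ndarray, scheme: str = "quartile") -> np.ndarray:
    """Quartile binning of RMSF into low/intermediate/high/highest.

    Ties on a quartile boundary go to the lower bin, so a uniform profile
    is all "low".
    """
    if scheme != "quartile":
        raise ValueError(f"unknown scheme {scheme!r}")
    r = np.asarray(rmsf, dtype=float)
    bounds = np.quantile(r, [0.25, 0.5, 0.75])
    return MOBILITY_CLASSES[np.searchsorted(bounds, r, side="left")]


@dataclass
class DeltaRMSF:
    """Per-residue RMSF difference (b - a) and the contiguous decrease runs."""

    res_ids: np.ndarray
    delta: np.ndarray
    decrease_runs: list[tuple[int, int, float]]  # (first res, last res, total decrease)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"res_id": self.res_ids, "delta_rmsf_A": self.delta})


def delta_rmsf(profile_a: MobilityProfile, profile_b: MobilityProfile,
               threshold: float = 0.1) -> DeltaRMSF:
    """Residue-wise RMSF change from condition a to condition b.

    Profiles must cover the same residues in the same order.  Contiguous
    runs where the change is below ``-threshold`` Å (mobility decrease,
    e.g. drug-damped loops) are reported largest-total-decrease first.
    """
    if not np.array_equal(profile_a.res_ids, profile_b.res_ids):
        raise ValueError("profiles cover different residue sets")
    delta = np.asarray(profile_b.rmsf) - np.asarray(profile_a.rmsf)
    res = np.asarray(profile_a.res_ids)
    runs = []
    start = None
    for j in range(len(delta) + 1):
        dec = j < len(delta) and delta[j] < -threshold
        if dec and start is None:
            start = j
        elif not dec and start is not None:
            runs.append((int(res[start]), int(res[j - 1]), float(delta[start:j].sum())))
            start = None
    runs.sort(key=lambda r: r[2])
    return DeltaRMSF(res, delta, runs)


def salt_bridge_occupancy(traj: Trajectory, cutoff: float = 4.0) -> pd.DataFrame:
    """Fraction of frames in which acidic–basic side-chain contacts exist.

    A bridge is counted in a frame when any carboxylate oxygen (Asp
    OD1/OD2, Glu OE1/OE2, or a C-terminal OXT) lies within ``cutoff`` Å of
    any Lys NZ or Arg NH1/NH2/NE.  Returns one row per residue pair with
    occupancy > 0, sorted by occupancy; Cα-only trajectories yield an empty
    result with a warning.
    """
    pairs = list(zip(traj.res_names, traj.atom_names))
    acid = np.array([(rn, an) in _ACIDIC or an == "OXT" for rn, an in pairs])
    base = np.array([(rn, an) in _BASIC for rn, an in pairs])
    ai = np.flatnonzero(acid)
    bi = np.flatnonzero(base)
    if len(ai) == 0 or len(bi) == 0:
        warnings.warn(
            "no salt-bridge-capable side-chain atoms found (Ca-only trajectory?)",
            stacklevel=2,
        )
        return pd.DataFrame(
            columns=["acid_res_name", "acid_res_id", "base_res_name",
                     "base_res_id", "occupancy"]
        )
    counts: dict[tuple, int] = {}
    for f in range(traj.n_frames):
        d = cdist(traj.coords[f, ai], traj.coords[f, bi])
        hit = d <= cutoff
        frame_pairs = set()
        for u, v in zip(*np.nonzero(hit)):
            frame_pairs.add((int(traj.res_ids[ai[u]]), int(traj.res_ids[bi[v]])))
        for key in frame_pairs:
            counts[key] = counts.get(key, 0) + 1
    name_of = dict(zip(traj.res_ids.tolist(), traj.res_names.tolist()))
    rows = [
        {
            "acid_res_name": name_of[a],
            "acid_res_id": a,
            "base_res_name": name_of[b],
            "base_res_id": b,
            "occupancy": c / traj.n_frames,
        }
        for (a, b), c in counts.items()
    ]
    columns = ["acid_res_name", "acid_res_id", "base_res_name", "base_res_id", "occupancy"]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)[columns].sort_values(
        ["occupancy", "acid_res_id", "base_res_id"], ascending=[False, True, True]
    )
    return df.reset_index(drop=True)
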
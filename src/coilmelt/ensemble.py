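"""Ensemble metrics for multi-model coordinate files.

Implements the standard trajectory observables for conformational ensembles
stored as multi-model PDB files: Kabsch least-squares superposition and
RMSD, per-residue RMSF about the mean structure, mass-weighted radius of
gyration, Shrake-Rupley solvent-accessible surface area partitioned into
hydrophobic and hydrophilic residue classes, salt bridges and interchain
hydrophobic contacts by distance cutoff, a Calpha-geometry helicity
assignment, per-pair distance timelines, and a per-frame report table with
trailing-window averages.

Coordinates are in Angstrom internally; Rg and SASA are reported in nm and
nm^2 for side-by-side reading with the molecular-dynamics literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "StructureEnsemble",
    "AtomSelection",
    "SasaPartition",
    "SaltBridge",
    "read_ensemble",
    "write_ensemble",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "sasa_partition",
    "salt_bridges",
    "hydrophobic_contacts",
    "helicity",
    "distance_timeline",
    "ensemble_report",
    "HYDROPHOBIC_RESIDUES",
    "BONDI_RADII",
]

#: Residues counted as hydrophobic for SASA partition and contact analysis.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "GLY"})

#: Bondi van der Waals radii (Angstrom) for the elements common in proteins.
BONDI_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
               "P": 1.80, "SE": 1.90}
DEFAULT_VDW_RADIUS = 1.5

ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                 "S": 32.06, "P": 30.974, "SE": 78.971}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

ACIDIC_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
BASIC_ATOMS = {"LYS": {"NZ"}, "ARG": {"NH1", "NH2", "NE"}}


class EnsembleFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class StructureEnsemble:
    """Ordered coordinate frames over a fixed atom table.

    ``atoms`` is a DataFrame with columns chain, resid, resname, name,
    element; ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    times_ps: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords second axis must match the atom table")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.times_ps is not None:
            self.times_ps = np.asarray(self.times_ps, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain"]))


@dataclass(frozen=True)
class AtomSelection:
    """Predicate over the atom table: chains, residue range, atom names."""

    chains: frozenset | None = None
    residue_range: tuple[int, int] | None = None
    atom_names: frozenset | None = None

    @classmethod
    def preset(cls, name: str) -> "AtomSelection":
        if name == "backbone":
            return cls(atom_names=frozenset(BACKBONE_ATOMS))
        if name == "calpha":
            return cls(atom_names=frozenset({"CA"}))
        if name == "all":
            return cls()
        raise KeyError(f"unknown selection preset {name!r}")

    def mask(self, atoms: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(atoms), dtype=bool)
        if self.chains is not None:
            m &= atoms["chain"].isin(self.chains).to_numpy()
        if self.residue_range is not None:
            lo, hi = self.residue_range
            r = atoms["resid"].to_numpy()
            m &= (r >= lo) & (r <= hi)
        if self.atom_names is not None:
            m &= atoms["name"].isin(self.atom_names).to_numpy()
        if not m.any():
            raise ValueError("selection matches no atoms")
        return m


def _resolve_selection(selection) -> AtomSelection:
    if selection is None:
        return AtomSelection()
    if isinstance(selection, str):
        return AtomSelection.preset(selection)
    return selection


@dataclass(frozen=True)
class SasaPartition:
    total_nm2: float
    hydrophobic_nm2: float
    hydrophilic_nm2: float
    per_residue: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        if abs(self.total_nm2 - self.hydrophobic_nm2 - self.hydrophilic_nm2) > 1e-6:
            raise ValueError("SASA classes must sum to the total")


@dataclass(frozen=True)
class SaltBridge:
    acidic: tuple  # (chain, resid, resname, atom)
    basic: tuple
    distance_A: float
    interchain: bool


# ---------------------------------------------------------------------------
# I/O (multi-model PDB via gemmi)
# ---------------------------------------------------------------------------


def read_ensemble(path, exclude_waters: bool = True) -> StructureEnsemble:
    """Read a (multi-)model PDB file into an ensemble.

    MODEL records define frames; all models must share the same atom table.
    HETATM waters are excluded by default.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise EnsembleFormatError(f"{path}: no models found")
    tables, frames = [], []
    for imodel, model in enumerate(st):
        rows, xyz = [], []
        for chain in model:
            for res in chain:
                if exclude_waters and res.name in ("HOH", "WAT"):
                    continue
                for atom in res:
                    rows.append((chain.name, res.seqid.num, res.name,
                                 atom.name, atom.element.name.upper()))
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        tables.append(rows)
        frames.append(np.array(xyz, dtype=float))
    ref = tables[0]
    for i, rows in enumerate(tables[1:], start=2):
        if rows != ref:
            raise EnsembleFormatError(
                f"{path}: model {i} atom table differs from model 1 "
                f"({len(rows)} vs {len(ref)} atoms)")
    atoms = pd.DataFrame(ref, columns=["chain", "resid", "resname", "name",
                                       "element"])
    return StructureEnsemble(atoms, np.stack(frames))


def write_ensemble(ensemble: StructureEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB file."""
    st = gemmi.Structure()
    st.name = "ensemble"
    atoms = ensemble.atoms
    for iframe in range(ensemble.n_frames):
        model = gemmi.Model(iframe + 1)
        coords = ensemble.coords[iframe]
        for chain_name in dict.fromkeys(atoms["chain"]):
            chain = gemmi.Chain(str(chain_name))
            sub = atoms[atoms["chain"] == chain_name]
            for resid in dict.fromkeys(sub["resid"]):
                res_rows = sub[sub["resid"] == resid]
                res = gemmi.Residue()
                res.name = str(res_rows.iloc[0]["resname"])
                res.seqid = gemmi.SeqId(int(resid), " ")
                for idx, row in res_rows.iterrows():
                    at = gemmi.Atom()
                    at.name = str(row["name"])
                    at.element = gemmi.Element(str(row["element"]))
                    x, y, z = coords[idx]
                    at.pos = gemmi.Position(float(x), float(y), float(z))
                    res.add_atom(at)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# superposition and fluctuation metrics
# ---------------------------------------------------------------------------


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray,
                     weights=None) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` in the
    least-squares sense; the rotation is proper (det = +1).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points for a unique superposition")
    if weights is None:
        w = np.ones(P.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = (w[:, None] * P0).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def rmsd_series(ensemble: StructureEnsemble, selection="backbone",
                reference: np.ndarray | int = 0, nm: bool = False) -> np.ndarray:
    """Per-frame RMSD to a reference after Kabsch superposition.

    ``reference`` may be a frame index or an explicit coordinate array for
    the full atom table. Set ``nm=True`` to report nanometres.
    """
    sel = _resolve_selection(selection).mask(ensemble.atoms)
    if isinstance(reference, (int, np.integer)):
        ref = ensemble.coords[int(reference)][sel]
    else:
        ref = np.asarray(reference, dtype=float)[sel]
    out = np.empty(ensemble.n_frames)
    for i in range(ensemble.n_frames):
        _, _, out[i] = kabsch_superpose(ref, ensemble.coords[i][sel])
    return out / 10.0 if nm else out


def rmsf(ensemble: StructureEnsemble, selection="calpha") -> pd.DataFrame:
    """Per-residue RMSF (Angstrom) about the superposed ensemble mean.

    Frames are superposed onto their mean structure, the mean is recomputed
    once, and RMSF_i = sqrt(<|x_i - <x_i>|^2>).
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF undefined for a single frame")
    sel = _resolve_selection(selection).mask(ensemble.atoms)
    X = ensemble.coords[:, sel, :].copy()
    mean = X.mean(axis=0)
    for _ in range(2):  # superpose to mean, recompute mean once
        for i in range(X.shape[0]):
            R, t, _ = kabsch_superpose(mean, X[i])
            X[i] = X[i] @ R.T + t
        mean = X.mean(axis=0)
    fluct = np.sqrt(((X - mean) ** 2).sum(axis=2).mean(axis=0))
    sub = ensemble.atoms[sel]
    return pd.DataFrame({"chain": sub["chain"].to_numpy(),
                         "resid": sub["resid"].to_numpy(),
                         "rmsf_A": fluct})


def radius_of_gyration(frame: np.ndarray, atoms: pd.DataFrame,
                       selection=None) -> float:
    """Mass-weighted radius of gyration in nm."""
    sel = _resolve_selection(selection).mask(atoms)
    xyz = np.asarray(frame, dtype=float)[sel]
    if xyz.shape[0] < 2:
        raise ValueError("Rg needs at least 2 atoms")
    masses = np.array([ATOMIC_MASSES.get(e, 12.0)
                       for e in atoms["element"].to_numpy()[sel]])
    if masses.sum() <= 0:
        raise ValueError("zero total mass")
    com = (masses[:, None] * xyz).sum(axis=0) / masses.sum()
    rg_A = math.sqrt(float((masses * ((xyz - com) ** 2).sum(axis=1)).sum()
                           / masses.sum()))
    return rg_A / 10.0


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def atom_sasa(frame: np.ndarray, elements, probe_radius: float = 1.4,
              n_sphere_points: int = 960, radii: dict | None = None) -> np.ndarray:
    """Shrake-Rupley accessible surface area per atom, in Angstrom^2.

    Test points on each atom's expanded sphere (vdW + probe) are rejected
    when inside any neighbouring expanded sphere; the accessible fraction
    times the sphere area gives the atom's SASA.
    """
    xyz = np.asarray(frame, dtype=float)
    table = dict(BONDI_RADII if radii is None else radii)
    r = np.array([table.get(str(e).upper(), DEFAULT_VDW_RADIUS)
                  for e in elements]) + probe_radius
    sphere = _sphere_points(n_sphere_points)
    tree = cKDTree(xyz)
    rmax = r.max()
    areas = np.empty(len(xyz))
    for i in range(len(xyz)):
        pts = xyz[i] + r[i] * sphere
        neighbours = [j for j in tree.query_ball_point(xyz[i], r[i] + rmax)
                      if j != i]
        if neighbours:
            d2 = ((pts[:, None, :] - xyz[neighbours][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (r[neighbours] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * r[i] ** 2
    return areas


def sasa_partition(frame: np.ndarray, atoms: pd.DataFrame,
                   probe_radius: float = 1.4, n_sphere_points: int = 960,
                   hydrophobic=HYDROPHOBIC_RESIDUES) -> SasaPartition:
    """Total SASA split into hydrophobic/hydrophilic residue classes (nm^2)."""
    areas = atom_sasa(frame, atoms["element"].to_numpy(),
                      probe_radius=probe_radius, n_sphere_points=n_sphere_points)
    df = atoms.assign(sasa_A2=areas)
    per_res = (df.groupby(["chain", "resid", "resname"], sort=False)["sasa_A2"]
               .sum().reset_index())
    per_res["hydrophobic"] = per_res["resname"].isin(hydrophobic)
    phobic = per_res.loc[per_res["hydrophobic"], "sasa_A2"].sum() / 100.0
    total = per_res["sasa_A2"].sum() / 100.0
    return SasaPartition(total_nm2=float(total), hydrophobic_nm2=float(phobic),
                         hydrophilic_nm2=float(total - phobic),
                         per_residue=per_res)


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------


def _charged_groups(atoms: pd.DataFrame, include_termini: bool = False):
    """Acidic-oxygen and basic-nitrogen atom groups keyed by residue."""
    acid, base = {}, {}
    for idx, row in atoms.iterrows():
        key = (row["chain"], int(row["resid"]), row["resname"])
        names = ACIDIC_ATOMS.get(row["resname"], set())
        if row["name"] in names or (include_termini and row["name"] == "OXT"):
            acid.setdefault(key, []).append(idx)
        names = BASIC_ATOMS.get(row["resname"], set())
        if row["name"] in names:
            base.setdefault(key, []).append(idx)
    if include_termini:
        for chain_name, sub in atoms.groupby("chain", sort=False):
            first = sub["resid"].min()
            nterm = sub[(sub["resid"] == first) & (sub["name"] == "N")]
            for idx, row in nterm.iterrows():
                base.setdefault((chain_name, int(first), row["resname"]),
                                []).append(idx)
    return acid, base


def salt_bridges(frame: np.ndarray, atoms: pd.DataFrame, cutoff: float = 4.0,
                 include_termini: bool = False) -> list[SaltBridge]:
    """Salt bridges: acidic-O / basic-N residue pairs within ``cutoff`` A.

    One bridge per residue pair (the minimum inter-group atom distance),
    flagged interchain when the residues sit on different chains.
    """
    xyz = np.asarray(frame, dtype=float)
    acid, base = _charged_groups(atoms, include_termini)
    bridges = []
    for akey, aidx in acid.items():
        for bkey, bidx in base.items():
            d = np.linalg.norm(xyz[aidx][:, None, :] - xyz[bidx][None, :, :],
                               axis=2)
            imin = np.unravel_index(np.argmin(d), d.shape)
            if d[imin] <= cutoff:
                bridges.append(SaltBridge(
                    acidic=(akey[0], akey[1], akey[2],
                            atoms.loc[aidx[imin[0]], "name"]),
                    basic=(bkey[0], bkey[1], bkey[2],
                           atoms.loc[bidx[imin[1]], "name"]),
                    distance_A=float(d[imin]),
                    interchain=akey[0] != bkey[0]))
    return bridges


def hydrophobic_contacts(frame: np.ndarray, atoms: pd.DataFrame,
                         cutoff: float = 5.0, interchain_only: bool = True,
                         hydrophobic=HYDROPHOBIC_RESIDUES):
    """Hydrophobic residue pairs with side-chain heavy atoms within cutoff.

    Returns ``(count, pairs)`` where each pair is
    ((chain, resid, resname), (chain, resid, resname), min_distance_A).
    Glycine contributes no side-chain atoms and cannot form contacts.
    """
    xyz = np.asarray(frame, dtype=float)
    side = atoms[atoms["resname"].isin(hydrophobic)
                 & ~atoms["name"].isin(BACKBONE_ATOMS)
                 & (atoms["element"] != "H")]
    groups = {key: list(sub.index) for key, sub in
              side.groupby(["chain", "resid", "resname"], sort=False)}
    keys = list(groups)
    pairs = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            ki, kj = keys[i], keys[j]
            if interchain_only and ki[0] == kj[0]:
                continue
            d = np.linalg.norm(xyz[groups[ki]][:, None, :]
                               - xyz[groups[kj]][None, :, :], axis=2).min()
            if d <= cutoff:
                pairs.append((ki, kj, float(d)))
    return len(pairs), pairs


# ---------------------------------------------------------------------------
# helicity
# ---------------------------------------------------------------------------

D13_RANGE = (4.7, 5.7)
D14_RANGE = (5.8, 6.7)
MIN_RUN = 4


def helicity(frame: np.ndarray, atoms: pd.DataFrame,
             min_chain_length: int = 5):
    """Percent helical residues from Calpha geometry.

    A residue index i passes when d(i, i+3) lies in [4.7, 5.7] A and
    d(i, i+4) in [5.8, 6.7] A; runs of at least four consecutive passing
    indices mark all covered residues (i through i+4) helical. Chains
    shorter than ``min_chain_length`` are excluded from the assignable set.
    Returns ``(percent, codes)`` with one 'H'/'-' code per Calpha of the
    assignable chains.
    """
    xyz = np.asarray(frame, dtype=float)
    ca = atoms[atoms["name"] == "CA"]
    percent_num = percent_den = 0
    codes = {}
    for chain_name, sub in ca.groupby("chain", sort=False):
        sub = sub.sort_values("resid")
        if len(sub) < min_chain_length:
            continue
        x = xyz[sub.index.to_numpy()]
        n = len(x)
        passing = np.zeros(n, dtype=bool)
        for i in range(n - 4):
            d13 = np.linalg.norm(x[i + 3] - x[i])
            d14 = np.linalg.norm(x[i + 4] - x[i])
            passing[i] = (D13_RANGE[0] <= d13 <= D13_RANGE[1]
                          and D14_RANGE[0] <= d14 <= D14_RANGE[1])
        helical = np.zeros(n, dtype=bool)
        run = 0
        for i in range(n):
            run = run + 1 if passing[i] else 0
            if passing[i] and run >= MIN_RUN:
                helical[i - run + 1:i + 5] = True
        codes[chain_name] = "".join("H" if h else "-" for h in helical)
        percent_num += int(helical.sum())
        percent_den += n
    if percent_den == 0:
        raise ValueError("no assignable chains (all shorter than "
                         f"{min_chain_length} residues)")
    return 100.0 * percent_num / percent_den, codes


# ---------------------------------------------------------------------------
# timelines and reports
# ---------------------------------------------------------------------------


def distance_timeline(ensemble: StructureEnsemble,
                      pairs: list[tuple]) -> pd.DataFrame:
    """Per-frame minimum inter-group distances for residue pairs.

    Each pair is ``((chain, resid), (chain, resid))`` and the distance is
    the minimum over all heavy-atom pairs between the two residues.
    """
    atoms = ensemble.atoms
    cols = {}
    for (c1, r1), (c2, r2) in pairs:
        i1 = atoms.index[(atoms["chain"] == c1) & (atoms["resid"] == r1)
                         & (atoms["element"] != "H")].to_numpy()
        i2 = atoms.index[(atoms["chain"] == c2) & (atoms["resid"] == r2)
                         & (atoms["element"] != "H")].to_numpy()
        if i1.size == 0:
            raise KeyError(f"residue {c1}/{r1} not found in the ensemble")
        if i2.size == 0:
            raise KeyError(f"residue {c2}/{r2} not found in the ensemble")
        series = np.empty(ensemble.n_frames)
        for f in range(ensemble.n_frames):
            xyz = ensemble.coords[f]
            series[f] = np.linalg.norm(
                xyz[i1][:, None, :] - xyz[i2][None, :, :], axis=2).min()
        cols[f"{c1}{r1}-{c2}{r2}"] = series
    return pd.DataFrame(cols)


def ensemble_report(ensemble: StructureEnsemble, selection="backbone",
                    trailing: int = 10, sasa_points: int = 240,
                    salt_bridge_cutoff: float = 4.0,
                    contact_cutoff: float = 5.0) -> pd.DataFrame:
    """Per-frame metric table plus a trailing-window mean row.

    Columns: RMSD (nm, to frame 0 over ``selection``), Rg (nm), percent
    helicity, hydrophobic/hydrophilic SASA (nm^2), salt-bridge count,
    interchain hydrophobic-contact count. The final row (index "mean")
    averages the last ``trailing`` frames, clipped to the trajectory length.
    """
    if trailing > ensemble.n_frames:
        import warnings
        warnings.warn("trailing window longer than the trajectory; clipped")
        trailing = ensemble.n_frames
    rmsd = rmsd_series(ensemble, selection=selection, nm=True)
    rows = []
    for f in range(ensemble.n_frames):
        xyz = ensemble.coords[f]
        part = sasa_partition(xyz, ensemble.atoms, n_sphere_points=sasa_points)
        pct, _ = helicity(xyz, ensemble.atoms)
        rows.append({
            "rmsd_nm": rmsd[f],
            "rg_nm": radius_of_gyration(xyz, ensemble.atoms),
            "helicity_pct": pct,
            "sasa_hydrophobic_nm2": part.hydrophobic_nm2,
            "sasa_hydrophilic_nm2": part.hydrophilic_nm2,
            "n_salt_bridges": len(salt_bridges(xyz, ensemble.atoms,
                                               cutoff=salt_bridge_cutoff)),
            "n_hydrophobic_contacts": hydrophobic_contacts(
                xyz, ensemble.atoms, cutoff=contact_cutoff)[0],
        })
    df = pd.DataFrame(rows)
    df.index.name = "frame"
    mean_row = df.tail(trailing).mean()
    mean_row.name = "mean"
    return pd.concat([df, mean_row.to_frame().T])
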
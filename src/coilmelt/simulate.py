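"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is seed-deterministic and emits the exact containers the
analysis operators consume: two-state melting curves with linear baselines,
CD spectra as basis mixtures, heptad-periodic sequences with planted charged
a/d sites, ideal alpha-helix and two-chain coiled-coil Calpha traces, and
coordinate ensembles with a prescribed per-residue fluctuation profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cd import CDSpectrum, reference_basis
from .ensemble import StructureEnsemble, kabsch_superpose
from .heptad import ProteinSequence, REGISTER_LETTERS
from .melt import GAS_CONSTANT_KJ, MeltCurve, gibbs_helmholtz

__all__ = [
    "MeltGenerator",
    "EnsembleGenerator",
    "gen_melt_curve",
    "gen_cd_spectrum",
    "gen_ideal_helix",
    "gen_coiled_coil",
    "gen_heptad_sequence",
    "perturb_ensemble",
    "build_salt_bridge_frame",
]

# Study conditions for the synthetic melt: the His-KLP64D/68D-S parameters
# with the instrument's 278-363 K ramp (0.5 K pitch keeps fits fast at no
# cost in identifiability).
DEFAULT_TM = 297.6
DEFAULT_DHM = 102.1
DEFAULT_DCP = 0.5624  # implied by that row's stationarity temperature


@dataclass(frozen=True)
class MeltGenerator:
    """Forward two-state melt model with linear baselines and Gaussian noise."""

    Tm_K: float = DEFAULT_TM
    dHm_kJ_mol: float = DEFAULT_DHM
    dCp_kJ_mol_K: float = DEFAULT_DCP
    y_N: float = -16000.0
    m_N: float = 10.0
    y_U: float = -3000.0
    m_U: float = 2.0
    t_start_K: float = 278.0
    t_stop_K: float = 363.0
    pitch_K: float = 0.5
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pitch_K <= 0:
            raise ValueError("pitch must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")

    def baseline_separation(self, T=None) -> float:
        """|unfolded - native| baseline gap at T (default: at Tm)."""
        T = self.Tm_K if T is None else T
        # slopes and intercepts are relative to T = t_start
        dt = T - self.t_start_K
        return abs((self.y_U + self.m_U * dt) - (self.y_N + self.m_N * dt))


def gen_melt_curve(gen: MeltGenerator) -> MeltCurve:
    """Simulate Y0(T) = (1-fU)*N(T) + fU*U(T) + noise from the forward model.

    Baseline lines are parameterized relative to the ramp start, i.e.
    native(T) = y_N + m_N*(T - t_start), and fU follows from the
    Gibbs-Helmholtz free energy via K = exp(-dG/RT).
    """
    T = np.arange(gen.t_start_K, gen.t_stop_K + 0.5 * gen.pitch_K, gen.pitch_K)
    if not (T[0] < gen.Tm_K < T[-1]):
        import warnings
        warnings.warn("Tm lies outside the temperature grid; the transition "
                      "will not be observed and fits will fail by design")
    dG = gibbs_helmholtz(T, gen.Tm_K, gen.dHm_kJ_mol, gen.dCp_kJ_mol_K)
    K = np.exp(-dG / (GAS_CONSTANT_KJ * T))
    fU = K / (1.0 + K)
    dt = T - gen.t_start_K
    native = gen.y_N + gen.m_N * dt
    unfolded = gen.y_U + gen.m_U * dt
    y = (1.0 - fU) * native + fU * unfolded
    if gen.noise_sigma > 0:
        rng = np.random.default_rng(gen.seed)
        y = y + rng.normal(0.0, gen.noise_sigma, size=y.shape)
    return MeltCurve(T, y)


def gen_cd_spectrum(helix_frac: float, coil_frac: float,
                    concentration_molar: float = 1e-5, path_cm: float = 0.1,
                    n_residues: int = 349, noise_mdeg: float = 0.0,
                    seed: int = 0, wavelength_nm=None) -> CDSpectrum:
    """CD spectrum of a helix/coil/sheet basis mixture, in raw millidegrees.

    Fractions must be non-negative with sum <= 1; the remainder goes to the
    sheet basis. The mean residue ellipticity mixture is converted back to
    the instrument scale with theta = [Theta]*10*C*l*N, then seeded Gaussian
    noise (in mdeg) is added.
    """
    if helix_frac < 0 or coil_frac < 0:
        raise ValueError("fractions must be non-negative")
    if helix_frac + coil_frac > 1.0 + 1e-12:
        raise ValueError("fractions must sum to at most 1")
    wl = np.arange(190.0, 260.0 + 0.25, 0.5) if wavelength_nm is None \
        else np.asarray(wavelength_nm, dtype=float)
    basis = reference_basis(wl)
    sheet_frac = 1.0 - helix_frac - coil_frac
    mre = (helix_frac * basis["helix"] + coil_frac * basis["coil"]
           + sheet_frac * basis["sheet"])
    theta = mre * 10.0 * concentration_molar * path_cm * n_residues
    if noise_mdeg > 0:
        rng = np.random.default_rng(seed)
        theta = theta + rng.normal(0.0, noise_mdeg, size=theta.shape)
    return CDSpectrum(wl, theta, concentration_molar, path_cm, n_residues)


# ---------------------------------------------------------------------------
# coordinate generators
# ---------------------------------------------------------------------------


def _ca_table(chain_ids, resids, resnames=None) -> pd.DataFrame:
    resnames = ["ALA"] * len(resids) if resnames is None else resnames
    return pd.DataFrame({"chain": chain_ids, "resid": resids,
                         "resname": resnames, "name": "CA", "element": "C"})


def gen_ideal_helix(n_residues: int, rise: float = 1.5, twist_deg: float = 100.0,
                    radius: float = 2.3, chain: str = "A",
                    start_resid: int = 1) -> StructureEnsemble:
    """Calpha trace of an ideal alpha-helix along z (single frame).

    Defaults (1.5 A rise, 100 deg twist, 2.3 A radius) give the canonical
    3.6 residues/turn with consecutive Calpha separations near 3.8 A.
    """
    if n_residues < 5:
        raise ValueError("need at least 5 residues")
    i = np.arange(n_residues)
    theta = np.deg2rad(twist_deg) * i
    xyz = np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                           rise * i])
    atoms = _ca_table([chain] * n_residues,
                      list(range(start_resid, start_resid + n_residues)))
    return StructureEnsemble(atoms, xyz[None, :, :])


def gen_coiled_coil(n_residues: int = 35, r0: float = 4.9, pitch: float = 140.0,
                    r1: float = 2.3, rise: float = 1.495,
                    phase_offset_deg: float = 180.0) -> StructureEnsemble:
    """Two-chain Calpha coiled coil from Crick-style parameters.

    Each chain is a minor helix (radius ``r1``, 3.5 residues per turn in the
    rotating frame) wound about a common z-axis superhelix of radius ``r0``
    and pitch ``pitch``; chain B starts ``phase_offset_deg`` around the
    superhelical axis. The 3.5-residue local period makes the hydrophobic
    seam repeat with the heptad period.
    """
    if n_residues < 14:
        raise ValueError("need at least 14 residues per chain")
    i = np.arange(n_residues)
    z = rise * i
    omega0 = 2.0 * math.pi / pitch          # superhelix twist per A of rise
    omega1 = 2.0 * math.pi / 3.5            # minor-helix twist per residue
    frames = []
    tables = []
    for chain, phi0 in (("A", 0.0), ("B", math.radians(phase_offset_deg))):
        phi = omega0 * z + phi0
        # local frame of the superhelical axis curve: radial normal n,
        # binormal b completes tangent t (helix Frenet frame is analytic)
        axis = np.column_stack([r0 * np.cos(phi), r0 * np.sin(phi), z])
        t = np.column_stack([-r0 * omega0 * np.sin(phi),
                             r0 * omega0 * np.cos(phi),
                             np.ones_like(z)])
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        nvec = np.column_stack([-np.cos(phi), -np.sin(phi), np.zeros_like(z)])
        b = np.cross(t, nvec)
        alpha = omega1 * i
        xyz = axis + r1 * (np.cos(alpha)[:, None] * nvec
                           + np.sin(alpha)[:, None] * b)
        frames.append(xyz)
        tables.append(_ca_table([chain] * n_residues, list(range(1, n_residues + 1))))
    atoms = pd.concat(tables, ignore_index=True)
    coords = np.concatenate(frames, axis=0)[None, :, :]
    return StructureEnsemble(atoms, coords)


HYDROPHOBIC_AD = "LIVM"
POLAR_OTHER = "EKQNASTR"
CHARGED = "DEKR"


def gen_heptad_sequence(n_heptads: int, charged_ad_positions=(), seed: int = 0,
                        phase: str = "a", numbering_offset: int = 1):
    """Heptad-periodic sequence with planted charged a/d sites.

    Hydrophobic residues (L/I/V/M) occupy a and d, charged/polar residues
    fill the other positions. ``charged_ad_positions`` lists full-protein
    residue numbers that must be a or d sites; those get a charged residue
    instead. Returns ``(ProteinSequence, register_string)`` ground truth.
    """
    if phase not in REGISTER_LETTERS:
        raise ValueError("phase must be one of a..g")
    rng = np.random.default_rng(seed)
    n = 7 * n_heptads
    p0 = REGISTER_LETTERS.index(phase)
    register = "".join(REGISTER_LETTERS[(p0 + k) % 7] for k in range(n))
    residues = []
    for k in range(n):
        if register[k] in "ad":
            residues.append(HYDROPHOBIC_AD[rng.integers(len(HYDROPHOBIC_AD))])
        else:
            residues.append(POLAR_OTHER[rng.integers(len(POLAR_OTHER))])
    for num in charged_ad_positions:
        k = num - numbering_offset
        if not 0 <= k < n:
            raise ValueError(f"planted position {num} outside the sequence")
        if register[k] not in "ad":
            raise ValueError(f"planted position {num} is register "
                             f"'{register[k]}', not a/d")
        residues[k] = CHARGED[rng.integers(len(CHARGED))]
    seq = ProteinSequence(f"synthetic_heptad_{seed}", "".join(residues),
                          numbering_offset)
    return seq, register


@dataclass(frozen=True)
class EnsembleGenerator:
    """Gaussian-fluctuation ensemble about a base structure.

    ``sigma_A`` is a per-residue isotropic displacement scale (one value per
    residue in base-atom order, or a scalar); optional random rigid motions
    exercise superposition invariance.
    """

    base: StructureEnsemble
    sigma_A: object = 0.5
    n_frames: int = 100
    seed: int = 0
    rigid_motion: bool = False

    def resolved_sigma(self) -> np.ndarray:
        atoms = self.base.atoms
        res_keys = list(dict.fromkeys(zip(atoms["chain"], atoms["resid"])))
        sig = np.asarray(self.sigma_A, dtype=float)
        if sig.ndim == 0:
            sig = np.full(len(res_keys), float(sig))
        if sig.shape != (len(res_keys),):
            raise ValueError(f"sigma profile must be scalar or length "
                             f"{len(res_keys)} (one per residue)")
        if np.any(sig < 0):
            raise ValueError("sigma must be non-negative")
        lookup = dict(zip(res_keys, sig))
        return np.array([lookup[(c, r)] for c, r in
                         zip(atoms["chain"], atoms["resid"])])


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def perturb_ensemble(gen: EnsembleGenerator) -> StructureEnsemble:
    """Frames = base + per-atom isotropic Gaussian noise (+ rigid motion).

    With per-residue displacement scale sigma_i, the expected RMSF about the
    mean structure is sigma_i * sqrt(3).
    """
    rng = np.random.default_rng(gen.seed)
    base_xyz = gen.base.coords[0]
    per_atom_sigma = gen.resolved_sigma()
    frames = np.empty((gen.n_frames, base_xyz.shape[0], 3))
    for f in range(gen.n_frames):
        xyz = base_xyz + rng.normal(size=base_xyz.shape) * per_atom_sigma[:, None]
        if gen.rigid_motion:
            R = _random_rotation(rng)
            t = rng.normal(scale=5.0, size=3)
            xyz = xyz @ R.T + t
        frames[f] = xyz
    return StructureEnsemble(gen.base.atoms.copy(), frames)


# ---------------------------------------------------------------------------
# geometric interaction fixtures
# ---------------------------------------------------------------------------

# Minimal heavy-atom templates (local coordinates, A) good enough to place
# charged/hydrophobic groups at controlled separations; not stereochemically
# refined side chains.
_RESIDUE_TEMPLATES = {
    "GLU": [("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (1.46, 0.0, 0.0)),
            ("C", "C", (2.0, 1.4, 0.0)), ("O", "O", (1.3, 2.4, 0.0)),
            ("CB", "C", (2.0, -0.8, 1.2)), ("CG", "C", (3.5, -0.9, 1.2)),
            ("CD", "C", (4.1, -1.7, 2.3)), ("OE1", "O", (5.3, -1.8, 2.4)),
            ("OE2", "O", (3.3, -2.3, 3.1))],
    "LYS": [("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (1.46, 0.0, 0.0)),
            ("C", "C", (2.0, 1.4, 0.0)), ("O", "O", (1.3, 2.4, 0.0)),
            ("CB", "C", (2.0, -0.8, 1.2)), ("CG", "C", (3.5, -0.9, 1.2)),
            ("CD", "C", (4.1, -1.7, 2.3)), ("CE", "C", (5.6, -1.8, 2.3)),
            ("NZ", "N", (6.2, -2.6, 3.4))],
    "LEU": [("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (1.46, 0.0, 0.0)),
            ("C", "C", (2.0, 1.4, 0.0)), ("O", "O", (1.3, 2.4, 0.0)),
            ("CB", "C", (2.0, -0.8, 1.2)), ("CG", "C", (3.5, -0.9, 1.2)),
            ("CD1", "C", (4.1, -1.7, 2.3)), ("CD2", "C", (4.1, -1.6, -0.05))],
}


def build_salt_bridge_frame(separation_A: float = 3.5,
                            pair: tuple[str, str] = ("GLU", "LYS"),
                            chains: tuple[str, str] = ("A", "B")):
    """Two side-chain-bearing residues with charged tips a set distance apart.

    Places the template residues so that the minimum distance between the
    first residue's charged-group atoms and the second's equals
    ``separation_A``. Returns ``(frame, atoms)`` ready for
    :func:`~coilmelt.ensemble.salt_bridges` or
    :func:`~coilmelt.ensemble.hydrophobic_contacts`.
    """
    tip_atoms = {"GLU": "OE1", "LYS": "NZ", "LEU": "CD1"}
    rows, xyz = [], []
    offsets = {}
    for k, (resname, chain) in enumerate(zip(pair, chains)):
        template = _RESIDUE_TEMPLATES[resname]
        tip = np.array(dict((n, c) for n, _, c in template)[tip_atoms[resname]])
        offsets[k] = tip
        for name, element, coord in template:
            rows.append((chain, 10 + k, resname, name, element))
            xyz.append(np.array(coord, dtype=float))
    atoms = pd.DataFrame(rows, columns=["chain", "resid", "resname", "name",
                                        "element"])
    xyz = np.array(xyz)
    # translate the second residue so the two tip atoms sit separation_A
    # apart along x, pointing the side chains at each other
    n0 = len(_RESIDUE_TEMPLATES[pair[0]])
    second = xyz[n0:]
    second[:] = -second  # mirror so the side chain points back
    shift = offsets[0] + np.array([separation_A, 0.0, 0.0]) - (-offsets[1])
    second += shift
    return xyz, atoms
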
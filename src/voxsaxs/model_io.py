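"""Atomic models, per-element scattering constants, and 1D profile I/O.

Atomic X-ray form factors use the standard four-Gaussian-plus-constant
parameterization (nine Cromer-Mann coefficients per atom type, from the
International Tables for Crystallography, Vol. C, Table 6.1.1.4):

    f(q) = sum_i a_i * exp(-b_i * (q / 4pi)^2) + c,   i = 1..4

van der Waals radii are Bondi values.  PDB parsing is delegated to gemmi;
experimental SWAXS profiles are plain whitespace-delimited text with
columns q [1/A], I, sigma.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import gemmi

logger = logging.getLogger(__name__)

FOUR_PI = 4.0 * np.pi


@dataclass(frozen=True)
class FormFactorCoeffs:
    """Gaussian form-factor parameterization of one atom type.

    ``a`` and ``b`` are the Gaussian amplitudes (electrons) and widths
    (A^2); ``c`` is the constant offset; ``n_electrons`` the integer
    electron count Z; ``vdw_radius`` the Bondi van der Waals radius in A.
    """

    a: tuple[float, ...]
    b: tuple[float, ...]
    c: float
    n_electrons: int
    vdw_radius: float

    def __post_init__(self) -> None:
        if abs(sum(self.a) + self.c - self.n_electrons) >= 0.1:
            raise ValueError(
                f"sum(a)+c = {sum(self.a) + self.c:.4f} inconsistent with "
                f"Z = {self.n_electrons}"
            )
        if any(bi <= 0 for bi in self.b):
            raise ValueError("all Gaussian widths b must be positive")


# (a1..a4, b1..b4, c, Z, Bondi vdW radius).  Radii without a Bondi value
# (metals) use common force-field defaults.
_TABLE = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879),
          (20.6593, 7.74039, 49.5519, 2.20159), 0.001305, 1, 1.20),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000),
          (20.8439, 10.2075, 0.568700, 51.6512), 0.215600, 6, 1.70),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.529, 7, 1.55),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800, 8, 1.52),
    "P": ((6.43450, 4.17910, 1.78000, 1.49080),
          (1.90670, 27.1570, 0.526000, 68.1645), 1.11490, 15, 1.80),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630),
          (1.46790, 22.2151, 0.253600, 56.1720), 0.866900, 16, 1.80),
    "NA": ((4.76260, 3.17360, 1.26740, 1.11280),
           (3.28500, 8.84220, 0.313600, 129.424), 0.676000, 11, 2.27),
    "MG": ((5.42040, 2.17350, 1.22690, 2.30730),
           (2.82750, 79.2611, 0.380800, 7.19370), 0.858400, 12, 1.73),
    "CL": ((11.4604, 7.19640, 6.25560, 1.64550),
           (0.010400, 1.16620, 18.5194, 47.7784), -9.55740, 17, 1.75),
    "CA": ((8.62660, 7.38730, 1.58990, 1.02110),
           (10.4421, 0.659900, 85.7484, 178.437), 1.37510, 20, 2.31),
    "FE": ((11.7695, 7.35730, 3.52220, 2.30450),
           (4.76110, 0.307200, 15.3535, 76.8805), 1.03690, 26, 2.00),
    "ZN": ((14.0743, 7.03180, 5.16520, 2.41000),
           (3.26550, 0.233300, 10.3163, 58.7097), 1.30410, 30, 1.39),
}

CROMER_MANN: dict[str, FormFactorCoeffs] = {
    el: FormFactorCoeffs(a, b, c, z, r) for el, (a, b, c, z, r) in _TABLE.items()
}


def get_coeffs(element: str) -> FormFactorCoeffs:
    """Look up the form-factor entry for a chemical symbol (case-insensitive)."""
    key = element.strip().upper()
    try:
        return CROMER_MANN[key]
    except KeyError:
        raise KeyError(f"no form-factor coefficients for element {element!r}")


def vdw_radius(element: str) -> float:
    return get_coeffs(element).vdw_radius


def form_factor(coeffs: FormFactorCoeffs, q) -> np.ndarray:
    """Evaluate f(q) = sum_i a_i exp(-b_i (q/4pi)^2) + c.  q in 1/A, >= 0."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("momentum transfer q must be non-negative")
    s2 = (q / FOUR_PI) ** 2
    out = np.full_like(s2, coeffs.c, dtype=float)
    for ai, bi in zip(coeffs.a, coeffs.b):
        out += ai * np.exp(-bi * s2)
    return out


# --- real-space form of the form factor -------------------------------------
#
# The real-space atomic density is the radial Fourier transform of f(q):
#
#   rho(r) = sum_i a_i (4pi / (b_i + B))^(3/2) exp(-4 pi^2 r^2 / (b_i + B))
#
# which requires dropping the constant offset c (a delta function in real
# space).  Rather than discard those electrons, the four (a_i, b_i) pairs
# are refit to the full nine-coefficient curve over q in [0, 8] 1/A; the
# refit reproduces f(q) to better than 1e-5 relative everywhere in that
# range, so the pure-Gaussian representation is exact for all practical q.

_REFIT_QMAX = 8.0
_refit_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def _refit_gaussians(a, b, c, z) -> tuple[np.ndarray, np.ndarray]:
    from scipy.optimize import curve_fit

    q = np.linspace(0.0, _REFIT_QMAX, 400)
    s2 = (q / FOUR_PI) ** 2
    y = sum(ai * np.exp(-bi * s2) for ai, bi in zip(a, b)) + c
    n = len(a)

    def model(q, *p):
        s2 = (q / FOUR_PI) ** 2
        return sum(p[i] * np.exp(-p[n + i] * s2) for i in range(n))

    total = sum(a)
    p0 = [ai * (total + c) / total for ai in a] + [max(bi, 0.05) for bi in b]
    popt, _ = curve_fit(model, q, y, p0=p0, maxfev=20000)
    return np.asarray(popt[:n]), np.asarray(popt[n:])


def real_space_coeffs(element: str) -> tuple[np.ndarray, np.ndarray]:
    """Offset-free Gaussian pairs (a_i, b_i) for the real-space density form.

    Cached per element; deterministic.
    """
    key = element.strip().upper()
    if key not in _refit_cache:
        cf = get_coeffs(key)
        _refit_cache[key] = _refit_gaussians(cf.a, cf.b, cf.c, cf.n_electrons)
    return _refit_cache[key]


def water_coeffs() -> FormFactorCoeffs:
    """Single-site composite form factor of a water molecule (O + 2 H).

    The eight Gaussians of oxygen and (doubled) hydrogen are concatenated;
    the spherically averaged single-center approximation carries the full
    10 electrons.
    """
    o = CROMER_MANN["O"]
    h = CROMER_MANN["H"]
    a = o.a + tuple(2.0 * ai for ai in h.a)
    b = o.b + h.b
    return FormFactorCoeffs(a, b, o.c + 2.0 * h.c, 10, 1.4)


_water_refit: list[tuple[np.ndarray, np.ndarray]] = []


def water_real_space_coeffs() -> tuple[np.ndarray, np.ndarray]:
    """Offset-free Gaussian pairs for the real-space water form factor."""
    if not _water_refit:
        w = water_coeffs()
        _water_refit.append(_refit_gaussians(w.a, w.b, w.c, w.n_electrons))
    return _water_refit[0]


# --- atomic models -----------------------------------------------------------


@dataclass
class AtomRecord:
    """One atom of a model: position (A), element, names, B-factor, occupancy."""

    position: np.ndarray
    element: str
    atom_name: str
    residue_name: str
    b_factor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.b_factor < 0:
            raise ValueError("B-factor must be non-negative")
        get_coeffs(self.element)  # fail early on unknown elements


def positions_of(atoms: list[AtomRecord]) -> np.ndarray:
    return np.array([a.position for a in atoms], dtype=float)


def radii_of(atoms: list[AtomRecord]) -> np.ndarray:
    return np.array([vdw_radius(a.element) for a in atoms], dtype=float)


def total_electrons(atoms: list[AtomRecord]) -> float:
    return float(sum(get_coeffs(a.element).n_electrons * a.occupancy for a in atoms))


def read_pdb(path, exclude_waters: bool = False) -> list[AtomRecord]:
    """Parse a PDB file into AtomRecords.

    Alternate locations are resolved by keeping the highest-occupancy
    conformer of each (residue, atom name).  Waters may be excluded.
    A model with no hydrogens triggers a warning: adjusted volumes and the
    calculated profile will be systematically wrong without them.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError, ValueError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise IOError(f"{path}: no model found")

    atoms: list[AtomRecord] = []
    n_altloc_dropped = 0
    for chain in st[0]:
        for residue in chain:
            if exclude_waters and residue.is_water():
                continue
            # resolve alternate locations: keep the highest-occupancy
            # conformer per atom name; blank-altloc atoms are always kept
            chosen: list[gemmi.Atom] = []
            by_name: dict[str, gemmi.Atom] = {}
            for atom in residue:
                if atom.altloc == "\0" or not atom.altloc:
                    chosen.append(atom)
                    continue
                prev = by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    if prev is not None:
                        n_altloc_dropped += 1
                    by_name[atom.name] = atom
                else:
                    n_altloc_dropped += 1
            chosen.extend(by_name.values())
            for atom in chosen:
                el = atom.element.name.upper()
                if el == "X" or not el:
                    raise ValueError(
                        f"unknown element for atom serial {atom.serial} "
                        f"({residue.name} {atom.name})"
                    )
                try:
                    get_coeffs(el)
                except KeyError as exc:
                    raise ValueError(
                        f"atom serial {atom.serial}: {exc}"
                    ) from exc
                atoms.append(
                    AtomRecord(
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        element=el,
                        atom_name=atom.name,
                        residue_name=residue.name,
                        b_factor=max(atom.b_iso, 0.0),
                        occupancy=atom.occ,
                    )
                )
    if not atoms:
        raise IOError(f"{path}: no ATOM/HETATM records")
    if n_altloc_dropped:
        logger.info("dropped %d lower-occupancy alternate conformers", n_altloc_dropped)
    if not any(a.element == "H" for a in atoms):
        warnings.warn(
            "model contains no hydrogen atoms; adjusted volumes and the "
            "calculated profile will be systematically wrong (add hydrogens "
            "with e.g. Reduce first)",
            stacklevel=2,
        )
    return atoms


def write_pdb(path, atoms: list[AtomRecord], res_ids: list[int] | None = None) -> None:
    """Write AtomRecords as minimal fixed-column ATOM records."""
    if res_ids is None:
        res_ids = [1] * len(atoms)
    with open(path, "w") as fh:
        for i, (a, rid) in enumerate(zip(atoms, res_ids), start=1):
            name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
            x, y, z = a.position
            fh.write(
                f"ATOM  {i:5d} {name:<4.4s} {a.residue_name:<3.3s} A{rid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                f"          {a.element:>2.2s}\n"
            )
        fh.write("END\n")


# --- 1D scattering profiles --------------------------------------------------


@dataclass
class ScatteringProfile:
    """(q, I, sigma) triples; q strictly increasing, all arrays equal length."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length differs from q")
        if self.intensity.shape != self.q.shape:
            raise ValueError("intensity length differs from q")
        if self.q.ndim != 1 or len(self.q) == 0:
            raise ValueError("profile must be a non-empty 1D set of points")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")

    def __len__(self) -> int:
        return len(self.q)


def read_profile(path, require_sigma: bool = False, q_scale: float = 1.0) -> ScatteringProfile:
    """Read a whitespace-delimited (q, I[, sigma]) text profile.

    Comment/header lines and rows with non-numeric fields are skipped;
    rows with non-positive sigma are dropped (count logged).  ``q_scale``
    rescales the q column (e.g. 0.1 to convert 1/nm to 1/A).
    """
    rows = []
    ncols = None
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith(("#", ";")):
                continue
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError:
                n_bad += 1
                continue
            if len(vals) < 2:
                n_bad += 1
                continue
            rows.append(vals)
            ncols = min(ncols, len(vals)) if ncols else len(vals)
    if not rows:
        raise IOError(f"{path}: no numeric data rows")
    if ncols < 2:
        raise IOError(f"{path}: fewer than 2 numeric columns")
    have_sigma = ncols >= 3
    if not have_sigma and require_sigma:
        raise IOError(f"{path}: sigma column required for fitting but absent")
    q = np.array([r[0] for r in rows]) * q_scale
    intensity = np.array([r[1] for r in rows])
    if have_sigma:
        sigma = np.array([r[2] for r in rows])
        keep = sigma > 0
        n_bad += int(np.sum(~keep))
        q, intensity, sigma = q[keep], intensity[keep], sigma[keep]
    else:
        warnings.warn(f"{path}: no sigma column, filling with 1.0", stacklevel=2)
        sigma = np.ones_like(q)
    if n_bad:
        logger.info("%s: dropped %d malformed/non-positive-sigma rows", path, n_bad)
    if len(q) == 0:
        raise IOError(f"{path}: empty after filtering")
    order = np.argsort(q)
    q, intensity, sigma = q[order], intensity[order], sigma[order]
    return ScatteringProfile(q, intensity, sigma)


def write_profile(path, profile: ScatteringProfile, header: str | None = None) -> None:
    """Write a profile as 2- or 3-column ASCII with full precision."""
    cols = [profile.q, profile.intensity]
    if profile.sigma is not None:
        cols.append(profile.sigma)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.8e}" for v in row) + "\n")
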
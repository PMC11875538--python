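"""Reading and writing of conformational ensembles, weight tables and SAXS curves.

The package analyses weighted conformational ensembles of two-chain
immunoglobulin light-chain dimers.  An ensemble arrives as a multi-model PDB
file; statistical weights arrive either explicitly or as final metadynamics
bias values (one row per model) that are converted to Boltzmann weights.
Experimental small-angle X-ray scattering (SAXS) curves arrive as the usual
3-column whitespace text (q, I, sigma).

Internal units: lengths in nm (PDB Angstrom are converted on read), scattering
vector q in inverse Angstrom, energies in kJ/mol, temperatures in kelvin.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "DomainArchitecture",
    "ConformerFrame",
    "WeightedEnsemble",
    "SAXSCurve",
    "read_ensemble",
    "write_ensemble",
    "read_saxs_curve",
    "write_table",
    "load_architecture",
]

#: Boltzmann constant in kJ mol^-1 K^-1
KB_KJMOL = 0.0083144621

# Standard atomic masses (Da) for elements that occur in protein PDB files.
_ELEMENT_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
    "MG": 24.305, "CA": 40.078, "NA": 22.990, "K": 39.098, "CL": 35.45,
}


def _element_mass(element: str) -> float:
    el = element.strip().upper()
    if el in _ELEMENT_MASSES:
        return _ELEMENT_MASSES[el]
    try:
        m = struc_info.mass(el)
    except Exception:
        m = None
    if m is None or m <= 0:
        raise ValueError(f"unknown element {element!r}: cannot assign a mass")
    return float(m)


@dataclass(frozen=True)
class DomainArchitecture:
    """Chain and residue-range mapping of a two-chain VL-linker-CL dimer.

    Residue ranges are inclusive intervals in the coordinate file's own
    (author) numbering.  The same ranges may be shared by both chains, which
    is the common case for a homodimer.

    Parameters
    ----------
    chain_ids:
        Exactly two chain identifiers, e.g. ``("A", "B")``.
    vl_range, linker_range, cl_range:
        Inclusive ``(first, last)`` residue intervals per chain, keyed by
        chain id.  A plain tuple is accepted and applied to both chains.
    display_numbering:
        Optional mapping from author residue number to a display label.
    """

    chain_ids: tuple[str, str]
    vl_range: Mapping[str, tuple[int, int]]
    linker_range: Mapping[str, tuple[int, int]]
    cl_range: Mapping[str, tuple[int, int]]
    display_numbering: Mapping[int, str] | None = None

    def __post_init__(self):
        if len(self.chain_ids) != 2 or len(set(self.chain_ids)) != 2:
            raise ValueError("architecture requires exactly two distinct chains")

        def _norm(r) -> dict[str, tuple[int, int]]:
            if isinstance(r, Mapping):
                return {c: (int(r[c][0]), int(r[c][1])) for c in self.chain_ids}
            lo, hi = int(r[0]), int(r[1])
            return {c: (lo, hi) for c in self.chain_ids}

        object.__setattr__(self, "vl_range", _norm(self.vl_range))
        object.__setattr__(self, "linker_range", _norm(self.linker_range))
        object.__setattr__(self, "cl_range", _norm(self.cl_range))
        for c in self.chain_ids:
            vl, lk, cl = self.vl_range[c], self.linker_range[c], self.cl_range[c]
            for lo, hi in (vl, lk, cl):
                if lo > hi:
                    raise ValueError(f"empty residue range {lo}-{hi} on chain {c}")
            if not (vl[1] < lk[0] and lk[1] < cl[0]):
                raise ValueError(
                    f"chain {c}: ranges must be disjoint and ordered VL < linker < CL"
                )

    @classmethod
    def default(cls) -> "DomainArchitecture":
        """Homodimer with VL 1-109, linker (hinge) 110-120, CL 121-214."""
        return cls(("A", "B"), (1, 109), (110, 120), (121, 214))

    def domain_range(self, domain: str, chain: str) -> tuple[int, int]:
        domain = domain.upper()
        table = {"VL": self.vl_range, "LINKER": self.linker_range,
                 "CL": self.cl_range}
        if domain not in table:
            raise ValueError(f"unknown domain {domain!r} (expected VL, LINKER or CL)")
        return table[domain][chain]


@dataclass(frozen=True)
class ConformerFrame:
    """One conformer: an atom table plus positions in nm.

    ``atoms`` columns: chain_id, res_id, res_name, atom_name, element, mass.
    """

    atoms: pd.DataFrame
    coords: np.ndarray  # (n_atoms, 3) nm

    def __post_init__(self):
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array does not match the atom table")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in frame")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def select(self, chain: str | None = None,
               res_range: tuple[int, int] | None = None,
               atom_name: str | None = None) -> np.ndarray:
        """Boolean mask over the atom table."""
        mask = np.ones(len(self.atoms), dtype=bool)
        if chain is not None:
            mask &= (self.atoms["chain_id"].to_numpy() == chain)
        if res_range is not None:
            rid = self.atoms["res_id"].to_numpy()
            mask &= (rid >= res_range[0]) & (rid <= res_range[1])
        if atom_name is not None:
            mask &= (self.atoms["atom_name"].to_numpy() == atom_name)
        return mask


@dataclass
class WeightedEnsemble:
    """A conformational ensemble with per-frame statistical weights.

    All frames share one atom table; coordinates are a dense
    ``(n_frames, n_atoms, 3)`` array in nm.  Weights are probabilities
    (non-negative, summing to one).
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    weights: np.ndarray
    replicate_id: str = ""
    temperature_K: float = 310.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords second axis does not match the atom table")
        if len(self.weights) != self.coords.shape[0]:
            raise ValueError(
                f"{len(self.weights)} weights for {self.coords.shape[0]} frames"
            )
        if self.n_frames < 1:
            raise ValueError("ensemble must contain at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in ensemble")
        if np.any(self.weights < 0):
            raise ValueError("negative frame weights")
        s = self.weights.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {s!r}, expected 1 within 1e-9")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def masses(self) -> np.ndarray:
        return self.atoms["mass"].to_numpy()

    def frame(self, i: int) -> ConformerFrame:
        return ConformerFrame(self.atoms, self.coords[i])

    def frames(self) -> Iterator[ConformerFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)


@dataclass
class SAXSCurve:
    """A small-angle scattering curve I(q) with optional uncertainties.

    q is in inverse Angstrom and strictly increasing; intensities are in
    arbitrary units.  ``sigma`` is None for back-calculated curves.
    ``nonpositive_I`` flags rows with I <= 0 (retained, e.g. noisy
    experimental tails).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.I.shape != self.q.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        # q = 0 is permitted for back-calculated curves (I(0) is defined);
        # experimental readers only ever produce q > 0
        if np.any(self.q < 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be non-negative and strictly increasing")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("non-finite intensities")
        if self.sigma is not None:
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0) or not np.all(np.isfinite(self.sigma)):
                raise ValueError("sigma must be finite and positive")

    @property
    def has_sigma(self) -> bool:
        return self.sigma is not None

    @property
    def nonpositive_I(self) -> np.ndarray:
        return self.I <= 0

    def __len__(self) -> int:
        return len(self.q)


# ---------------------------------------------------------------------------
# ensembles


def _stack_to_tables(stack: struc.AtomArrayStack) -> tuple[pd.DataFrame, np.ndarray]:
    arr0 = stack[0]
    elements = np.asarray(arr0.element)
    masses = np.array([_element_mass(e) for e in elements])
    atoms = pd.DataFrame({
        "chain_id": np.asarray(arr0.chain_id),
        "res_id": np.asarray(arr0.res_id, dtype=int),
        "res_name": np.asarray(arr0.res_name),
        "atom_name": np.asarray(arr0.atom_name),
        "element": elements,
        "mass": masses,
    })
    coords_nm = np.asarray(stack.coord, dtype=float) / 10.0  # A -> nm
    return atoms, coords_nm


def read_weight_table(path: str | Path, n_frames: int,
                      temperature_K: float) -> np.ndarray:
    """Read a per-frame weight TSV: column ``weight`` or ``bias_kJmol``.

    Rows bind to models positionally.  Bias values are converted to
    normalized Boltzmann weights at the given temperature.
    """
    from .reweighting import bias_to_weights

    table = pd.read_csv(path, sep=r"\s+", comment="#")
    if len(table) != n_frames:
        raise ValueError(
            f"weight table has {len(table)} rows but the ensemble has "
            f"{n_frames} models"
        )
    if "weight" in table.columns:
        w = table["weight"].to_numpy(dtype=float)
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            bad = int(np.flatnonzero(~np.isfinite(w) | (w < 0))[0])
            raise ValueError(f"invalid weight at row {bad}")
        s = w.sum()
        if s <= 0:
            raise ValueError("weights sum to zero")
        return w / s
    if "bias_kJmol" in table.columns:
        bias = table["bias_kJmol"].to_numpy(dtype=float)
        return bias_to_weights(bias, temperature_K).values
    raise ValueError(
        "weight table must have a 'weight' or 'bias_kJmol' column, got "
        f"{list(table.columns)}"
    )


def read_ensemble(coord_path: str | Path,
                  architecture: DomainArchitecture | None = None,
                  weight_path: str | Path | None = None,
                  temperature_K: float = 310.0,
                  replicate_id: str = "") -> WeightedEnsemble:
    """Read a multi-model PDB (plus optional weight/bias TSV) as an ensemble.

    Frames are taken in file order.  Without a weight table the ensemble is
    uniformly weighted.  If an architecture is given, every chain and residue
    range it names is checked against the atom table.
    """
    pdb = PDBFile.read(str(coord_path))
    try:
        stack = pdb.get_structure()  # raises if models differ in atom table
    except Exception as exc:
        raise ValueError(
            f"{coord_path}: models do not share one atom table ({exc})"
        ) from exc
    atoms, coords = _stack_to_tables(stack)

    if architecture is not None:
        present = set(atoms["chain_id"])
        for c in architecture.chain_ids:
            if c not in present:
                raise ValueError(
                    f"chain {c!r} of the architecture is absent from "
                    f"{coord_path} (found {sorted(present)})"
                )
            for dom in ("VL", "LINKER", "CL"):
                lo, hi = architecture.domain_range(dom, c)
                sel = ((atoms["chain_id"] == c)
                       & (atoms["res_id"] >= lo) & (atoms["res_id"] <= hi))
                if not sel.any():
                    raise ValueError(
                        f"{dom} range {lo}-{hi} on chain {c} matches no residue"
                    )

    n = coords.shape[0]
    if weight_path is None:
        weights = np.full(n, 1.0 / n)
    else:
        weights = read_weight_table(weight_path, n, temperature_K)
    return WeightedEnsemble(atoms, coords, weights,
                            replicate_id=replicate_id,
                            temperature_K=temperature_K)


def write_ensemble(ensemble: WeightedEnsemble, coord_path: str | Path,
                   weight_path: str | Path | None = None) -> None:
    """Write an ensemble as a multi-model PDB, optionally with a weight TSV."""
    n_atoms = ensemble.n_atoms
    arr = struc.AtomArray(n_atoms)
    arr.chain_id = ensemble.atoms["chain_id"].to_numpy(dtype="U4")
    arr.res_id = ensemble.atoms["res_id"].to_numpy(dtype=int)
    arr.res_name = ensemble.atoms["res_name"].to_numpy(dtype="U5")
    arr.atom_name = ensemble.atoms["atom_name"].to_numpy(dtype="U6")
    arr.element = ensemble.atoms["element"].to_numpy(dtype="U2")
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    stack = struc.stack([arr] * ensemble.n_frames)
    stack.coord = ensemble.coords * 10.0  # nm -> A
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(coord_path))
    if weight_path is not None:
        tab = pd.DataFrame({"frame": np.arange(ensemble.n_frames),
                            "weight": ensemble.weights})
        write_table(tab, weight_path)


# ---------------------------------------------------------------------------
# SAXS curves


def read_saxs_curve(path: str | Path, q_unit: str = "A^-1") -> SAXSCurve:
    """Read a 3-column (q, I, sigma) or 2-column (q, I) scattering curve.

    Lines that do not parse as 2-3 floats (headers, comments, footers) are
    skipped.  ``q_unit`` may be ``"A^-1"`` (default) or ``"nm^-1"``; in the
    latter case q is converted to inverse Angstrom.
    """
    rows: list[tuple[float, ...]] = []
    ncols: set[int] = set()
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) not in (2, 3):
            continue
        try:
            vals = tuple(float(p) for p in parts)
        except ValueError:
            continue
        rows.append(vals)
        ncols.add(len(vals))
    if not rows:
        raise ValueError(f"{path}: no numeric (q, I[, sigma]) rows found")
    data = np.array([r[:2] for r in rows])
    q, I = data[:, 0], data[:, 1]
    if ncols == {3}:
        sigma = np.array([r[2] for r in rows])
    else:
        sigma = None  # mixed or absent third column: sigma unavailable
    if q_unit.lower() in ("nm^-1", "nm-1", "1/nm"):
        q = q / 10.0
    elif q_unit.lower() not in ("a^-1", "a-1", "1/a", "ang^-1", "angstrom^-1"):
        raise ValueError(f"unknown q unit {q_unit!r}")
    order_ok = np.all(np.diff(q) > 0)
    if not order_ok:
        raise ValueError(f"{path}: q values are not strictly increasing")
    return SAXSCurve(q, I, sigma)


# ---------------------------------------------------------------------------
# tabular output


def write_table(records, path: str | Path) -> None:
    """Write tabular records as TSV with a header at full float precision.

    Accepts a DataFrame, a list of dataclass instances, or a list of dicts.
    Refuses to write an empty table.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    elif isinstance(records, Sequence) and len(records) > 0 and dataclasses.is_dataclass(records[0]):
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    else:
        df = pd.DataFrame(records)
    if len(df) == 0:
        raise ValueError("refusing to write an empty table")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# configuration


def load_architecture(path: str | Path) -> tuple[DomainArchitecture, dict]:
    """Load a domain-architecture YAML config.

    Expected keys: ``chains`` (list of two ids) and per-chain or shared
    ``vl``, ``linker``, ``cl`` inclusive ranges; optional ``temperature_K``
    and ``q_unit``.  Returns the architecture plus the remaining options.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    chains = tuple(cfg["chains"])

    def _rng(key):
        v = cfg[key]
        if isinstance(v, Mapping):
            return {c: tuple(v[c]) for c in chains}
        return tuple(v)

    arch = DomainArchitecture(chains, _rng("vl"), _rng("linker"), _rng("cl"))
    opts = {k: v for k, v in cfg.items()
            if k not in ("chains", "vl", "linker", "cl")}
    return arch, opts
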
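"""Reading and writing of state models, mode tables and spectra.

File formats
------------
State model
    JSON object with keys ``state_label``, ``charge``, ``elements``,
    ``masses_amu``, ``geometry_angstrom`` (flat 3n array x1,y1,z1,...),
    ``frequencies_cm1``, ``modes_massweighted`` (row-major 3n x n_v nested
    array), optional ``energy_eV``, ``energy_at_other_minimum_eV`` and
    ``linear``.
Mode table
    TSV with columns ``omega_cm1``, ``huang_rhys``, optional ``lambda_eV``
    and ``assignment``; ``#``-prefixed lines are comments.
Spectrum
    Two-column TSV ``wavenumber_cm1``, ``intensity`` with ``#`` metadata
    header lines (state basis, sigma, normalization).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import AtomSet, StateHarmonicModel, ValidationError, VibronicModeTable

_REQUIRED_KEYS = (
    "state_label",
    "charge",
    "elements",
    "masses_amu",
    "geometry_angstrom",
    "frequencies_cm1",
    "modes_massweighted",
)


def read_state_model(path) -> StateHarmonicModel:
    """Load a validated :class:`StateHarmonicModel` from a JSON file."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    missing = [k for k in _REQUIRED_KEYS if k not in data]
    if missing:
        raise ValidationError(f"{path.name}: missing field(s) {missing}")
    atoms = AtomSet(tuple(data["elements"]), np.asarray(data["masses_amu"], float))
    modes = np.asarray(data["modes_massweighted"], float)
    if modes.ndim == 1:  # tolerate a flat row-major dump
        n_v = len(data["frequencies_cm1"])
        modes = modes.reshape(3 * atoms.n, n_v)
    return StateHarmonicModel(
        state_label=data["state_label"],
        charge=int(data["charge"]),
        atoms=atoms,
        geometry=np.asarray(data["geometry_angstrom"], float),
        frequencies=np.asarray(data["frequencies_cm1"], float),
        mode_matrix=modes,
        energy=data.get("energy_eV"),
        energy_at_other_minimum=data.get("energy_at_other_minimum_eV"),
        linear=bool(data.get("linear", False)),
    )


def write_state_model(model: StateHarmonicModel, path) -> None:
    """Write a state model to the JSON schema (round-trips to 1e-12)."""
    data = {
        "state_label": model.state_label,
        "charge": model.charge,
        "elements": list(model.atoms.elements),
        "masses_amu": model.atoms.masses.tolist(),
        "geometry_angstrom": model.geometry.tolist(),
        "frequencies_cm1": model.frequencies.tolist(),
        "modes_massweighted": model.mode_matrix.tolist(),
        "linear": model.linear,
    }
    if model.energy is not None:
        data["energy_eV"] = model.energy
    if model.energy_at_other_minimum is not None:
        data["energy_at_other_minimum_eV"] = model.energy_at_other_minimum
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


# ----------------------------------------------------------------------
def read_mode_table(path, state_basis: str = "neutral") -> VibronicModeTable:
    """Load a per-mode (omega, S, lambda, assignment) TSV table.

    lambda is recomputed as hbar*omega*S where the column is absent or
    blank, and consistency-checked (warning on mismatch) where given.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip() for c in df.columns]
    if "omega_cm1" not in df.columns or "huang_rhys" not in df.columns:
        raise ValidationError(
            f"{path}: mode table needs columns omega_cm1 and huang_rhys, "
            f"found {list(df.columns)}"
        )
    if len(df) == 0:
        raise ValidationError(f"{path}: no rows in mode table")
    lam = df["lambda_eV"].tolist() if "lambda_eV" in df.columns else None
    assignment = (
        df["assignment"].fillna("").tolist() if "assignment" in df.columns else None
    )
    return VibronicModeTable.from_columns(
        state_basis,
        df["omega_cm1"].to_numpy(float),
        df["huang_rhys"].to_numpy(float),
        lam,
        assignment,
    )


def write_mode_table(table: VibronicModeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# state_basis: {table.state_basis}\n")
        fh.write("omega_cm1\thuang_rhys\tlambda_eV\tassignment\n")
        for r in table.rows:
            fh.write(f"{r.omega:.6g}\t{r.huang_rhys:.10g}\t{r.reorg:.10g}\t{r.assignment}\n")


# ----------------------------------------------------------------------
def write_spectrum(spectrum, path) -> None:
    """Write a convolved spectrum as a two-column TSV with metadata header."""
    grid = np.asarray(spectrum.grid, float)
    if grid.size == 0:
        raise ValidationError("spectrum grid is empty")
    dg = np.diff(grid)
    if np.any(dg <= 0):
        msg = "duplicate abscissa" if np.any(dg == 0) else "non-monotone grid"
        raise ValidationError(f"spectrum grid must be strictly increasing ({msg})")
    with open(path, "w") as fh:
        fh.write(f"# sigma_cm1: {spectrum.sigma}\n")
        fh.write(f"# normalization: {spectrum.normalization}\n")
        if getattr(spectrum, "basis", None):
            fh.write(f"# state_basis: {spectrum.basis}\n")
        fh.write("wavenumber_cm1\tintensity\n")
        for x, y in zip(grid, spectrum.values):
            fh.write(f"{x:.10g}\t{y:.12g}\n")


def read_spectrum(path):
    """Read a spectrum TSV back into a :class:`~vibronic.spectra.ConvolvedSpectrum`."""
    from .spectra import ConvolvedSpectrum

    meta = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    return ConvolvedSpectrum(
        grid=df["wavenumber_cm1"].to_numpy(float),
        values=df["intensity"].to_numpy(float),
        sigma=float(meta.get("sigma_cm1", 0) or 0),
        normalization=meta.get("normalization", "none"),
        basis=meta.get("state_basis"),
    )
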
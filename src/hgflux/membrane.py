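"""Free-energy profiles for membrane crossing and barrier-derived rate ratios.

A potential of mean force (PMF) along the membrane normal ``z`` quantifies the
Gibbs free-energy cost for a species (a 4-5 nm HgS nanoparticle, or a dissolved
Hg(II) complex) to move from bulk water into a phospholipid bilayer.  This
module reads such profiles, anchors them to the aqueous baseline, partitions
the coordinate into the four conventional membrane regions

    I   lipid alkyl chains            z in (-inf, 1.0] nm
    II  phospholipid headgroups       z in (1.0, 2.0] nm
    III headgroup-water interface     z in (2.0, 2.5] nm
    IV  bulk aqueous phase            z  > 2.5 nm

and converts barrier-height differences between two species into the fold
difference of their passive crossing rates under transition-state theory with
a shared kinetic prefactor:

    k_A / k_B = exp((dG_B - dG_A) / (R T))

Energies are in kJ/mol throughout, distances in nm, temperatures in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "FreeEnergyProfile",
    "RegionPartition",
    "BarrierResult",
    "read_pmf",
    "write_pmf",
    "normalize_reference",
    "barrier_height",
    "crossing_rate_ratio",
    "log10_crossing_rate_ratio",
    "arrhenius_rate",
]

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: z values larger than this are taken to indicate Angstrom (or other) units.
_MAX_PLAUSIBLE_Z_NM = 100.0

DEFAULT_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class RegionPartition:
    """Partition of the membrane-normal coordinate into four regions.

    ``boundaries`` are the three cut points (nm) separating regions
    I|II, II|III and III|IV.  Intervals are closed on the right, so the
    aqueous region IV is strictly ``z > boundaries[-1]``.
    """

    boundaries: tuple[float, float, float] = (1.0, 2.0, 2.5)
    names: tuple[str, str, str, str] = ("I", "II", "III", "IV")

    def __post_init__(self) -> None:
        if len(self.boundaries) != 3:
            raise ValueError("exactly three boundaries define four regions")
        if len(self.names) != 4:
            raise ValueError("exactly four region names required")
        b = np.asarray(self.boundaries, dtype=float)
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")

    def region_of(self, z: float | np.ndarray) -> np.ndarray | str:
        """Region name(s) containing ``z`` (right-closed intervals)."""
        idx = np.searchsorted(np.asarray(self.boundaries), z, side="left")
        names = np.asarray(self.names, dtype=object)
        out = names[idx]
        return out if isinstance(idx, np.ndarray) else str(out)

    def aqueous_mask(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z) > self.boundaries[-1]

    def membrane_mask(self, z: np.ndarray) -> np.ndarray:
        """Regions I-III: membrane interior plus both interfaces."""
        return np.asarray(z) <= self.boundaries[-1]


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Sampled free-energy profile dG(z) along the membrane normal.

    z is strictly ascending (nm); dg in kJ/mol; ``label`` identifies the
    permeating species; ``temperature_K`` is attached at load/config time.
    """

    z: np.ndarray
    dg: np.ndarray
    label: str = ""
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        dg = np.asarray(self.dg, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "dg", dg)
        if z.ndim != 1 or dg.ndim != 1:
            raise ValueError("z and dg must be one-dimensional")
        if z.size != dg.size:
            raise ValueError("z and dg must have the same length")
        if z.size < 2:
            raise ValueError("profile needs at least 2 samples")
        if not np.all(np.isfinite(z)) or not np.all(np.isfinite(dg)):
            raise ValueError("profile contains non-finite values")
        if not np.all(np.diff(z) > 0):
            raise ValueError("z must be strictly increasing")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")
        if np.max(np.abs(z)) > _MAX_PLAUSIBLE_Z_NM:
            raise ValueError(
                f"z range up to {np.max(np.abs(z)):g} is implausible for nm; "
                "if the file is in Angstrom, convert to nm before loading"
            )

    def __len__(self) -> int:
        return int(self.z.size)


@dataclass(frozen=True)
class BarrierResult:
    """Maximum free energy over the membrane regions, relative to water."""

    height: float  # kJ/mol above the aqueous baseline
    z_at_max: float  # nm
    region: str


def read_pmf(
    path: str | Path,
    dialect: str = "plain",
    label: str | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> FreeEnergyProfile:
    """Read a two-column (z, dG) profile from text.

    ``dialect='plain'`` skips blank lines and '#' comments; ``dialect='xvg'``
    additionally skips '@' directive lines as written by common MD tooling.
    Columns may be separated by whitespace or commas.  Rows are sorted by z;
    duplicate z values are rejected.
    """
    path = Path(path)
    if dialect not in ("plain", "xvg"):
        raise ValueError(f"unknown dialect {dialect!r}; use 'plain' or 'xvg'")
    if not path.exists():
        raise FileNotFoundError(path)

    zs: list[float] = []
    gs: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if dialect == "xvg" and line.startswith("@"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
        try:
            zs.append(float(parts[0]))
            gs.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric payload") from exc

    if len(zs) < 2:
        raise ValueError(f"{path}: fewer than 2 usable rows")
    z = np.asarray(zs)
    dg = np.asarray(gs)
    order = np.argsort(z, kind="stable")
    z, dg = z[order], dg[order]
    if np.any(np.diff(z) == 0):
        dup = z[:-1][np.diff(z) == 0][0]
        raise ValueError(f"{path}: duplicate z value {dup:g}")
    return FreeEnergyProfile(z=z, dg=dg, label=label or path.stem,
                             temperature_K=temperature_K)


def write_pmf(profile: FreeEnergyProfile, path: str | Path) -> None:
    """Write a profile as plain two-column text with a one-line header."""
    path = Path(path)
    lines = [f"# {profile.label} T={profile.temperature_K:g} K"]
    for zi, gi in zip(profile.z, profile.dg):
        lines.append(f"{zi:.17g} {gi:.17g}")
    path.write_text("\n".join(lines) + "\n")


def normalize_reference(
    profile: FreeEnergyProfile,
    partition: RegionPartition | None = None,
) -> FreeEnergyProfile:
    """Shift dG so the mean over the aqueous region (IV) is zero.

    Using the region mean rather than the endpoint value makes the baseline
    robust to sampling noise at the edge of the profile.  Idempotent.
    """
    partition = partition or RegionPartition()
    mask = partition.aqueous_mask(profile.z)
    if not np.any(mask):
        raise ValueError(
            f"no samples in aqueous region (z > {partition.boundaries[-1]:g} nm)"
        )
    shift = float(np.mean(profile.dg[mask]))
    return replace(profile, dg=profile.dg - shift)


def barrier_height(
    profile: FreeEnergyProfile,
    partition: RegionPartition | None = None,
) -> BarrierResult:
    """Highest free energy over regions I-III of a baseline-normalized profile.

    The raw sample maximum is used (no interpolation); argmax ties break
    toward smaller z, i.e. toward the membrane interior.
    """
    partition = partition or RegionPartition()
    mask = partition.membrane_mask(profile.z)
    if not np.any(mask):
        raise ValueError("no samples in membrane regions I-III")
    z_m = profile.z[mask]
    dg_m = profile.dg[mask]
    i = int(np.argmax(dg_m))  # first occurrence = smallest z on ties
    return BarrierResult(
        height=float(dg_m[i]),
        z_at_max=float(z_m[i]),
        region=str(partition.region_of(float(z_m[i]))),
    )


def _log_ratio(dg_low: float, dg_high: float, temperature_K: float) -> float:
    if temperature_K <= 0:
        raise ValueError("temperature_K must be positive")
    if not (math.isfinite(dg_low) and math.isfinite(dg_high)):
        raise ValueError("barriers must be finite")
    return (dg_high - dg_low) * 1000.0 / (GAS_CONSTANT * temperature_K)


def crossing_rate_ratio(
    dg_low: float, dg_high: float, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Fold difference in passive crossing rate between two barriers.

    Returns exp((dg_high - dg_low)*1000 / (R*T)): the factor by which the
    low-barrier species crosses faster, assuming a shared prefactor.  For
    very large barrier differences the result overflows to ``inf``; use
    :func:`log10_crossing_rate_ratio` in that regime.
    """
    ln_ratio = _log_ratio(dg_low, dg_high, temperature_K)
    if ln_ratio > 709.0:  # exp overflow threshold for float64
        return math.inf
    return math.exp(ln_ratio)


def log10_crossing_rate_ratio(
    dg_low: float, dg_high: float, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> float:
    """log10 of :func:`crossing_rate_ratio`, safe for any barrier difference."""
    return _log_ratio(dg_low, dg_high, temperature_K) / math.log(10.0)


def arrhenius_rate(
    dg: float, prefactor: float, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Absolute barrier-crossing rate ``A * exp(-dG/(R T))`` in 1/s.

    The ratio of two such rates at equal prefactor equals
    :func:`crossing_rate_ratio`.
    """
    if prefactor <= 0:
        raise ValueError("prefactor must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature_K must be positive")
    return prefactor * math.exp(-dg * 1000.0 / (GAS_CONSTANT * temperature_K))
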
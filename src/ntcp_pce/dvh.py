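"""Dose-volume histograms: container, CSV interchange, and scalar dose metrics.

A :class:`DoseVolumeHistogram` stores the *differential* DVH of one structure:
uniformly spaced dose bins (default width 0.1 Gy, matching typical treatment
planning increments of 10 cGy) and the fraction of the structure volume in
each bin.  All volumes are fractions of the structure volume; absolute volumes
are normalised on construction.  Doses attributed to a bin are its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MalformedInputError

_EDGE_TOL = 1e-12
_NORM_TOL = 1e-9

#: Recognised CSV dialects for :func:`read_dvh_table` / :func:`write_dvh_table`.
DIALECTS = ("differential", "cumulative")


@dataclass(frozen=True)
class DoseVolumeHistogram:
    """Differential DVH of a single structure.

    Parameters
    ----------
    structure_name:
        Label of the contoured structure (e.g. ``"heart"``).
    bin_edges:
        Dose bin edges in Gy, strictly increasing with uniform width.
        ``len(bin_edges) == len(diff_volume) + 1``.
    diff_volume:
        Non-negative fractional volume per bin; normalised to sum to 1.
    """

    structure_name: str
    bin_edges: np.ndarray
    diff_volume: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        vols = np.asarray(self.diff_volume, dtype=float)
        if edges.ndim != 1 or vols.ndim != 1 or edges.size != vols.size + 1:
            raise MalformedInputError(
                "bin_edges must be 1-D with one more entry than diff_volume"
            )
        if vols.size == 0:
            raise MalformedInputError("empty DVH")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise MalformedInputError("bin_edges must be strictly increasing")
        if np.ptp(widths) > _EDGE_TOL * max(1.0, widths[0]):
            raise MalformedInputError("bin width must be uniform")
        if np.any(vols < -_NORM_TOL):
            raise MalformedInputError("negative bin volume")
        vols = np.clip(vols, 0.0, None)
        total = vols.sum()
        if total <= 0:
            raise MalformedInputError("DVH has zero total volume")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "diff_volume", vols / total)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def midpoints(self) -> np.ndarray:
        """Dose attributed to each bin (bin centre), Gy."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def cumulative(self) -> np.ndarray:
        """Fractional volume receiving at least the dose of each *lower* bin edge.

        Non-increasing; the first entry is 1 by normalisation.
        """
        return self.diff_volume[::-1].cumsum()[::-1]

    def max_dose(self) -> float:
        """Highest bin midpoint carrying any volume, Gy."""
        nz = np.nonzero(self.diff_volume > 0)[0]
        return float(self.midpoints[nz[-1]])


def mean_dose(dvh: DoseVolumeHistogram) -> float:
    """Volume-weighted mean dose sum_i v_i * D_i in Gy (D_i at bin midpoints)."""
    return float(np.dot(dvh.diff_volume, dvh.midpoints))


def volume_at_dose(dvh: DoseVolumeHistogram, threshold: float) -> float:
    """Fraction of the structure receiving at least ``threshold`` Gy (V_x).

    Step function over bin midpoints: a bin counts iff its midpoint dose is
    >= the threshold. Non-increasing in the threshold with V(0) = 1.
    """
    if threshold < 0:
        raise MalformedInputError("threshold must be >= 0")
    return float(dvh.diff_volume[dvh.midpoints >= threshold].sum())


def _edges_from_midpoints(mids: np.ndarray, default_width: float = 0.1) -> np.ndarray:
    if mids.size == 1:
        w = default_width
    else:
        w = float(mids[1] - mids[0])
    return np.concatenate([mids - w / 2.0, [mids[-1] + w / 2.0]])


def _sniff_dialect(path: Path) -> str | None:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "dialect:" in line:
                    return line.split("dialect:", 1)[1].strip()
                continue
            break
    return None


def read_dvh_table(path: str | Path, dialect: str | None = None) -> list[DoseVolumeHistogram]:
    """Read DVHs from the long-format interchange CSV.

    Columns: ``structure, dose_gy, volume_fraction``; one row per bin (or per
    cumulative point).  The dialect — ``differential`` (dose_gy = bin
    midpoints) or ``cumulative`` (dose_gy = bin edges, volume = fraction
    receiving >= that dose) — is taken from the ``# dialect:`` header comment
    unless passed explicitly.  Cumulative inputs are converted to differential
    form by adjacent differencing.
    """
    path = Path(path)
    if not path.exists():
        raise MalformedInputError(f"no such file: {path}")
    if dialect is None:
        dialect = _sniff_dialect(path)
    if dialect not in DIALECTS:
        raise ConfigurationError(
            f"unknown DVH dialect {dialect!r}; expected one of {DIALECTS}"
        )
    df = pd.read_csv(path, comment="#")
    required = {"structure", "dose_gy", "volume_fraction"}
    if not required.issubset(df.columns):
        raise MalformedInputError(f"DVH table must have columns {sorted(required)}")
    out: list[DoseVolumeHistogram] = []
    for name, grp in df.groupby("structure", sort=False):
        grp = grp.sort_values("dose_gy")
        dose = grp["dose_gy"].to_numpy(dtype=float)
        vol = grp["volume_fraction"].to_numpy(dtype=float)
        if np.any(vol < 0):
            raise MalformedInputError(f"negative volume in structure {name!r}")
        if dialect == "differential":
            out.append(DoseVolumeHistogram(str(name), _edges_from_midpoints(dose), vol))
        else:
            if np.any(np.diff(vol) > _NORM_TOL):
                raise MalformedInputError(
                    f"cumulative volumes must be non-increasing (structure {name!r})"
                )
            diff = -np.diff(vol)
            out.append(DoseVolumeHistogram(str(name), dose, diff))
    return out


def write_dvh_table(
    dvhs: Iterable[DoseVolumeHistogram],
    path: str | Path,
    dialect: str = "differential",
) -> None:
    """Write DVHs to the interchange CSV with a ``# dialect:`` header comment."""
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown DVH dialect {dialect!r}")
    rows = []
    for dvh in dvhs:
        if dialect == "differential":
            dose, vol = dvh.midpoints, dvh.diff_volume
        else:
            dose = dvh.bin_edges
            vol = np.concatenate([dvh.cumulative(), [0.0]])
        for d, v in zip(dose, vol):
            rows.append((dvh.structure_name, d, v))
    df = pd.DataFrame(rows, columns=["structure", "dose_gy", "volume_fraction"])
    with open(path, "w") as fh:
        fh.write(f"# dialect: {dialect}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.12g")
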
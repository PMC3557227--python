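"""Peak lists, peak→fragment assignment, and cleavage-propensity time courses.

The observable in a limited-proteolysis/MS time course is, per condition
(free or bound), replicate and quench time, a list of (m/z, intensity)
peaks.  Peaks are matched to theoretical singly protonated fragment masses;
uniquely assigned intensities are then converted into the *relative
cleavage propensity* of each site — the share of total assigned intensity
carried by fragments whose boundary is that site:

    P(s, t) = sum of intensities of uniquely assigned fragments bounded by s
              -----------------------------------------------------------
              sum of intensities of all uniquely assigned peaks (incl. intact)

P is scale-free (invariant under rescaling all intensities at a time point)
and bounded in [0, 1].  It is computed per replicate, then the replicate
mean and standard deviation are stored.  The per-site × per-time table is
serialised in a plain-text ``.csgnu`` dialect (see :func:`write_csgnu`).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .digestion import Fragment

__all__ = [
    "PROTON_MASS",
    "DEFAULT_TIME_POINTS",
    "PeakList",
    "Assignment",
    "PropensityTable",
    "PeakListFormatError",
    "read_peaklist",
    "parse_peaklist_filename",
    "assign_peaks",
    "cleavage_propensity",
    "write_csgnu",
    "read_csgnu",
]

#: Mass of a proton, Da — singly protonated [M+H]+ ions are assumed.
PROTON_MASS = 1.00728

#: Default quench-time series of the time-course protocol, minutes.
DEFAULT_TIME_POINTS = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0)


class PeakListFormatError(ValueError):
    pass


class CsgnuFormatError(ValueError):
    pass


@dataclass
class PeakList:
    """One spectrum's peak list plus its experimental metadata."""

    protein_id: str
    condition: str  # "free" | "bound"
    replicate: int
    time_point: float  # minutes
    peaks: np.ndarray  # (n, 2) [m/z, intensity], sorted by m/z

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if self.condition not in ("free", "bound"):
            raise ValueError(f"condition must be free|bound, got {self.condition!r}")
        if len(self.peaks) and np.any(self.peaks[:, 1] < 0):
            raise PeakListFormatError("negative intensity in peak list")
        order = np.argsort(self.peaks[:, 0], kind="stable")
        self.peaks = self.peaks[order]

    def __len__(self) -> int:
        return len(self.peaks)


_FILENAME_RE = re.compile(
    r"(?P<protein>.+)_(?P<condition>free|bound)_(?:rep)?(?P<rep>\d+)_"
    r"(?P<time>\d+(?:\.\d+)?)min$"
)


def parse_peaklist_filename(path) -> dict:
    """Extract metadata from ``<protein>_<free|bound>_<rep>_<time>min.csv``."""
    stem = Path(path).stem
    m = _FILENAME_RE.match(stem)
    if m is None:
        raise PeakListFormatError(
            f"{path}: filename does not match <protein>_<free|bound>_<rep>_<time>min"
        )
    return {
        "protein_id": m.group("protein"),
        "condition": m.group("condition"),
        "replicate": int(m.group("rep")),
        "time_point": float(m.group("time")),
    }


def read_peaklist(path, fmt: str | None = None, metadata: dict | None = None) -> PeakList:
    """Read a two-column (m/z, intensity) CSV/TSV peak list.

    Metadata comes from the filename convention unless supplied explicitly.
    Malformed rows raise with the offending line number; an empty file
    yields an empty peak list with a warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    sep = "\t" if fmt == "tsv" else ","
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in re.split(rf"[{sep}\s]+", line) if p]
            if len(parts) != 2:
                raise PeakListFormatError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                mz, inten = float(parts[0]), float(parts[1])
            except ValueError:
                raise PeakListFormatError(
                    f"{path}:{lineno}: non-numeric value in {parts!r}"
                ) from None
            if inten < 0:
                raise PeakListFormatError(f"{path}:{lineno}: negative intensity")
            rows.append((mz, inten))
    if not rows:
        warnings.warn(f"{path}: empty peak list", stacklevel=2)
    meta = metadata or parse_peaklist_filename(path)
    return PeakList(peaks=np.array(rows, dtype=float).reshape(-1, 2), **meta)


@dataclass
class Assignment:
    """A peak with its candidate fragments within mass tolerance."""

    mz: float
    intensity: float
    candidates: list[tuple[Fragment, float, float]]  # (fragment, err_Da, err_ppm)

    @property
    def status(self) -> str:
        n = len(self.candidates)
        return "unassigned" if n == 0 else "unique" if n == 1 else "ambiguous"

    @property
    def fragment(self) -> Fragment | None:
        """The fragment, for uniquely assigned peaks only."""
        return self.candidates[0][0] if self.status == "unique" else None


def assign_peaks(
    pl: PeakList,
    frags: Sequence[Fragment],
    tol: float = 0.5,
    tol_unit: str = "Da",
) -> list[Assignment]:
    """Match peaks to theoretical [M+H]+ m/z of fragments within tolerance.

    ``tol_unit`` is ``"Da"`` (default 0.5 Da, MALDI linear mode) or
    ``"ppm"``.  Unassigned is a status, never an error.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if tol_unit not in ("Da", "ppm"):
        raise ValueError(f"tol_unit must be Da|ppm, got {tol_unit!r}")
    theo = np.array([f.mass + PROTON_MASS for f in frags])
    out = []
    for mz, inten in pl.peaks:
        limit = tol if tol_unit == "Da" else tol * mz / 1e6
        errs = mz - theo if len(theo) else np.empty(0)
        idx = np.flatnonzero(np.abs(errs) <= limit)
        cands = [
            (frags[i], float(errs[i]), float(errs[i] / theo[i] * 1e6)) for i in idx
        ]
        cands.sort(key=lambda c: abs(c[1]))
        out.append(Assignment(float(mz), float(inten), cands))
    return out


@dataclass
class PropensityTable:
    """Relative cleavage propensity per site × time (replicate mean ± SD).

    This is the content of a ``.csgnu`` "3D plot" file: for each cleavage
    site (P1 residue number) and each quench time, the share of assigned MS
    intensity attributable to fragments bounded by that site.
    """

    protein_id: str
    condition: str
    sites: np.ndarray  # (S,) int residue numbers, ascending
    times: np.ndarray  # (T,) minutes, ascending
    propensity: np.ndarray  # (S, T) replicate mean, in [0, 1] (NaN = undefined)
    propensity_sd: np.ndarray  # (S, T)

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.propensity = np.asarray(self.propensity, dtype=float)
        self.propensity_sd = np.asarray(self.propensity_sd, dtype=float)
        S, T = len(self.sites), len(self.times)
        if self.propensity.shape != (S, T) or self.propensity_sd.shape != (S, T):
            raise ValueError("propensity matrices must be (n_sites, n_times)")
        finite = self.propensity[np.isfinite(self.propensity)]
        if np.any(finite < -1e-9) or np.any(finite > 1 + 1e-9):
            raise ValueError("propensity outside [0, 1]")

    def mean_over_time(self, skip_t0: bool = True) -> np.ndarray:
        """Per-site mean propensity over time points (t > 0 by default)."""
        cols = self.times > 0 if skip_t0 else np.ones_like(self.times, bool)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.propensity[:, cols], axis=1)

    def max_over_time(self, skip_t0: bool = True) -> np.ndarray:
        cols = self.times > 0 if skip_t0 else np.ones_like(self.times, bool)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmax(self.propensity[:, cols], axis=1)


def _replicate_propensity(
    assignments: Sequence[Assignment],
    sites: Sequence[int],
    ambiguous: str,
) -> np.ndarray:
    """P(s) for one replicate/time from its assignments; NaN if nothing assigned."""
    per_site = dict.fromkeys(sites, 0.0)
    total = 0.0
    for a in assignments:
        if a.status == "unique":
            frags = [(a.candidates[0][0], 1.0)]
        elif a.status == "ambiguous" and ambiguous == "split":
            w = 1.0 / len(a.candidates)
            frags = [(c[0], w) for c in a.candidates]
        else:
            continue
        total += a.intensity
        for frag, w in frags:
            for s in frag.boundary_sites:
                if s in per_site:
                    per_site[s] += w * a.intensity
    if total <= 0:
        return np.full(len(sites), np.nan)
    return np.array([per_site[s] / total for s in sites])


def cleavage_propensity(
    assignments: Mapping[tuple[int, float], Sequence[Assignment]],
    sites: Sequence[int],
    protein_id: str,
    condition: str,
    ambiguous: str = "exclude",
) -> PropensityTable:
    """Build a propensity table from per-(replicate, time) assignments.

    Parameters
    ----------
    assignments : mapping ``(replicate, time_min) -> list of Assignment``
    sites : P1 residue numbers the table should cover (cleavage sites).
    ambiguous : ``"exclude"`` (default — ambiguous peaks ignored) or
        ``"split"`` (intensity divided equally among candidates).

    A time point with zero assigned intensity in a replicate yields NaN
    there (flagged via a warning) and is ignored in the replicate mean.
    """
    if ambiguous not in ("exclude", "split"):
        raise ValueError("ambiguous must be exclude|split")
    if not assignments:
        raise ValueError("no assignments given")
    sites = sorted(int(s) for s in sites)
    reps = sorted({k[0] for k in assignments})
    times = np.array(sorted({k[1] for k in assignments}))
    S, T, R = len(sites), len(times), len(reps)
    per_rep = np.full((R, S, T), np.nan)
    for (rep, t), asg in assignments.items():
        per_rep[reps.index(rep), :, list(times).index(t)] = _replicate_propensity(
            asg, sites, ambiguous
        )
    if np.isnan(per_rep).any():
        warnings.warn(
            f"{protein_id}/{condition}: undefined propensity at some "
            "replicate/time points (no assigned intensity)",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_rep, axis=0)
        sd = np.nanstd(per_rep, axis=0, ddof=1) if R > 1 else np.zeros((S, T))
    return PropensityTable(protein_id, condition, np.array(sites), times, mean, sd)


# --- .csgnu text dialect ---------------------------------------------------
#
# Comment header (# protein, # condition, # times), then one block per site:
# rows "site time propensity sd", blank line between site blocks.


def write_csgnu(pt: PropensityTable, path) -> None:
    """Write a propensity table in the package's ``.csgnu`` text dialect."""
    with open(path, "w") as fh:
        fh.write(f"# protein {pt.protein_id}\n")
        fh.write(f"# condition {pt.condition}\n")
        fh.write("# times " + " ".join(f"{t:g}" for t in pt.times) + "\n")
        for i, s in enumerate(pt.sites):
            for j, t in enumerate(pt.times):
                fh.write(
                    f"{s} {t:g} {pt.propensity[i, j]:.6f} "
                    f"{pt.propensity_sd[i, j]:.6f}\n"
                )
            fh.write("\n")


def read_csgnu(path) -> PropensityTable:
    """Read a ``.csgnu`` file written by :func:`write_csgnu`."""
    protein = condition = None
    times: list[float] | None = None
    rows: dict[int, dict[float, tuple[float, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if not parts:
                    continue
                if parts[0] == "protein":
                    protein = " ".join(parts[1:])
                elif parts[0] == "condition":
                    condition = parts[1]
                elif parts[0] == "times":
                    times = [float(x) for x in parts[1:]]
                continue
            parts = line.split()
            if len(parts) != 4:
                raise CsgnuFormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                s, t, p, sd = int(parts[0]), *map(float, parts[1:])
            except ValueError:
                raise CsgnuFormatError(f"{path}:{lineno}: non-numeric row") from None
            rows.setdefault(s, {})[t] = (p, sd)
    if protein is None or condition is None or times is None:
        raise CsgnuFormatError(f"{path}: missing header (# protein/condition/times)")
    sites = sorted(rows)
    P = np.empty((len(sites), len(times)))
    SD = np.empty_like(P)
    for i, s in enumerate(sites):
        for j, t in enumerate(times):
            if t not in rows[s]:
                raise CsgnuFormatError(f"{path}: site {s} missing time {t:g}")
            P[i, j], SD[i, j] = rows[s][t]
    return PropensityTable(protein, condition, np.array(sites), np.array(times), P, SD)
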
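"""Rupture-force extraction and dynamic-force-spectroscopy statistics.

Consumes force time/extension series in the xvg dialect (plain columns with
'#'/'@' comment headers, as written by GROMACS pull code or by the bundled
toy simulator), extracts the per-trajectory rupture force F_max (the peak of
the force profile), and aggregates many trajectories into the standard
summary: mean rupture force F_av with sample SD, a histogram, and the most
probable rupture force (mode of the histogram).  Two pulling directions are
compared by mean/mode differences, pooled effect size and a fixed-seed
bootstrap interval.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ForceCurve",
    "RuptureStats",
    "DirectionComparison",
    "read_force_xvg",
    "write_force_xvg",
    "peak_force",
    "aggregate_ruptures",
    "compare_directions",
]


@dataclasses.dataclass
class ForceCurve:
    """Force series: time ps, optional extension nm, force kJ/mol/nm."""

    time: np.ndarray
    force: np.ndarray
    extension: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.extension is not None:
            self.extension = np.asarray(self.extension, dtype=float)
            if len(self.extension) != len(self.time):
                raise ValueError("extension and time lengths differ")
        if len(self.time) != len(self.force):
            raise ValueError("time and force lengths differ")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)


def read_force_xvg(path: str | Path) -> ForceCurve:
    """Parse an xvg-dialect force file.

    Lines starting with '#' or '@' are headers.  Numeric rows of two columns
    are (time, force); three columns are (time, extension, force).
    """
    path = Path(path)
    rows: list[list[float]] = []
    width: int | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            fields = line.split()
            try:
                values = [float(x) for x in fields]
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed numeric row {line!r}"
                ) from exc
            if len(values) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(values)}"
                )
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise ValueError(f"{path}:{lineno}: ragged row")
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no numeric rows")
    data = np.array(rows)
    if width == 2:
        return ForceCurve(time=data[:, 0], force=data[:, 1])
    return ForceCurve(time=data[:, 0], extension=data[:, 1], force=data[:, 2])


def write_force_xvg(curve: ForceCurve, path: str | Path, title: str = "") -> Path:
    """Write a force curve in the xvg dialect (full float precision)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"@    title \"{title or 'pull force'}\"\n")
        fh.write("@    xaxis  label \"Time (ps)\"\n")
        fh.write("@    yaxis  label \"Force (kJ/mol/nm)\"\n")
        if curve.extension is not None:
            fh.write("# columns: time_ps extension_nm force_kJ_mol_nm\n")
            for t, x, f in zip(curve.time, curve.extension, curve.force):
                fh.write(f"{t:.10g} {x:.10g} {f:.10g}\n")
        else:
            fh.write("# columns: time_ps force_kJ_mol_nm\n")
            for t, f in zip(curve.time, curve.force):
                fh.write(f"{t:.10g} {f:.10g}\n")
    return path


def peak_force(
    curve: ForceCurve, smoothing_window: int = 1
) -> tuple[float, float]:
    """Rupture force F_max of one trajectory and the time of the peak.

    The global maximum of the (optionally moving-average smoothed) force.
    A window of 1 disables smoothing and is exactly the sample maximum.
    """
    if len(curve) < 3:
        raise ValueError("force curve needs at least 3 samples")
    if smoothing_window < 1:
        raise ValueError("smoothing window must be >= 1")
    f = curve.force
    if smoothing_window > 1:
        w = min(smoothing_window, len(f))
        kernel = np.ones(w) / w
        f = np.convolve(f, kernel, mode="same")
    i = int(np.argmax(f))
    return float(f[i]), float(curve.time[i])


@dataclasses.dataclass
class RuptureStats:
    """Summary of per-trajectory rupture forces along one pulling direction."""

    f_max_values: np.ndarray
    mean: float
    sd: float | None  # sample SD (n-1); None for n = 1
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    mode_bin_center: float | None
    n: int
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "mode_bin_center": self.mode_bin_center,
            "f_max_values": [float(x) for x in self.f_max_values],
            "histogram_counts": [int(c) for c in self.histogram_counts],
            "histogram_edges": [float(e) for e in self.histogram_edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuptureStats":
        return cls(
            f_max_values=np.asarray(d["f_max_values"], dtype=float),
            mean=float(d["mean"]),
            sd=None if d["sd"] is None else float(d["sd"]),
            histogram_counts=np.asarray(d["histogram_counts"], dtype=int),
            histogram_edges=np.asarray(d["histogram_edges"], dtype=float),
            mode_bin_center=(
                None
                if d["mode_bin_center"] is None
                else float(d["mode_bin_center"])
            ),
            n=int(d["n"]),
            label=d.get("label", ""),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RuptureStats":
        return cls.from_dict(json.loads(Path(path).read_text()))


MIN_N_FOR_HISTOGRAM = 5


def aggregate_ruptures(
    fmax_values: Sequence[float],
    bin_rule: str | int | Sequence[float] = "fd",
    label: str = "",
) -> RuptureStats:
    """Mean +/- sample SD, histogram and most probable rupture force.

    ``bin_rule`` is anything numpy.histogram accepts; the default is
    Freedman-Diaconis.  The most probable force is the centre of the
    highest-count bin (ties broken toward the lower bin); it requires at
    least 5 trajectories, as does the histogram.
    """
    values = np.asarray(list(fmax_values), dtype=float)
    if values.size < 1:
        raise ValueError("need at least one rupture force")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else None
    if values.size >= MIN_N_FOR_HISTOGRAM:
        if values.max() == values.min():
            # degenerate: all identical; a single bin keeps counts meaningful
            edges = np.array([values[0] - 0.5, values[0] + 0.5])
            counts = np.array([values.size])
        else:
            counts, edges = np.histogram(values, bins=bin_rule)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mode = float(centers[int(np.argmax(counts))])  # argmax -> lowest tie
    else:
        counts = np.array([], dtype=int)
        edges = np.array([], dtype=float)
        mode = None
    return RuptureStats(
        f_max_values=values,
        mean=mean,
        sd=sd,
        histogram_counts=counts,
        histogram_edges=edges,
        mode_bin_center=mode,
        n=int(values.size),
        label=label,
    )


@dataclasses.dataclass(frozen=True)
class DirectionComparison:
    """Mean/mode rupture-force differences between two pulling directions."""

    mean_difference: float
    mode_difference: float | None
    pooled_sd: float
    effect_size: float  # Cohen's d with pooled SD
    bootstrap_interval: tuple[float, float]  # 95% CI of the mean difference
    bootstrap_resamples: int
    bootstrap_seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compare_directions(
    stats_a: RuptureStats,
    stats_b: RuptureStats,
    bootstrap_resamples: int = 10_000,
    bootstrap_seed: int = 2018,
) -> DirectionComparison:
    """Compare rupture-force statistics of direction A against direction B.

    Reports mean and mode differences (A - B), the pooled-SD effect size and
    a fixed-seed percentile bootstrap 95% interval for the mean difference.
    """
    if stats_a.n < MIN_N_FOR_HISTOGRAM or stats_b.n < MIN_N_FOR_HISTOGRAM:
        raise ValueError("direction comparison needs n >= 5 on both sides")
    a, b = stats_a.f_max_values, stats_b.f_max_values
    mean_diff = float(a.mean() - b.mean())
    mode_diff = (
        None
        if stats_a.mode_bin_center is None or stats_b.mode_bin_center is None
        else float(stats_a.mode_bin_center - stats_b.mode_bin_center)
    )
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    pooled = float(
        np.sqrt(
            ((stats_a.n - 1) * var_a + (stats_b.n - 1) * var_b)
            / (stats_a.n + stats_b.n - 2)
        )
    )
    if pooled > 0:
        effect = mean_diff / pooled
    else:
        effect = 0.0 if mean_diff == 0 else float("inf") * np.sign(mean_diff)
    rng = np.random.default_rng(bootstrap_seed)
    ra = rng.choice(a, size=(bootstrap_resamples, a.size), replace=True)
    rb = rng.choice(b, size=(bootstrap_resamples, b.size), replace=True)
    diffs = ra.mean(axis=1) - rb.mean(axis=1)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return DirectionComparison(
        mean_difference=mean_diff,
        mode_difference=mode_diff,
        pooled_sd=pooled,
        effect_size=float(effect),
        bootstrap_interval=(float(lo), float(hi)),
        bootstrap_resamples=bootstrap_resamples,
        bootstrap_seed=bootstrap_seed,
    )
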
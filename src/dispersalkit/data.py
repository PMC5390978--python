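"""Domain types and data handling for mark-release-recapture (MRR) studies.

The study design places baited panel traps in concentric rings around a
central release point: full rings at 40, 80, 160 and 320 m, and eight
equidistant clusters of five traps each on the 640 m and 960 m circles.
Two grids are supported: ``D170`` (6/12/24/48 traps on the inner rings,
170 traps total) and ``D200`` (24/24/24/48, 200 traps total).

All coordinates are metric, with the release point at the origin, x
pointing east and y pointing north.  Trap azimuths start at due north and
proceed clockwise; only distances and axis projections enter any analysis,
so the angular phase is an arbitrary but fixed convention.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trap",
    "TrapLayout",
    "ReleaseEvent",
    "CaptureRecord",
    "RingSummary",
    "MechanisticDecomposition",
    "build_trap_layout",
    "aggregate_by_ring",
    "load_fixture",
    "read_traps_csv",
    "write_traps_csv",
    "read_releases_csv",
    "write_releases_csv",
    "read_captures_csv",
    "write_captures_csv",
    "ring_summary_frame",
]

RING_DISTANCES_M = (40, 80, 160, 320, 640, 960)

#: traps per ring for each named design; the outer two rings hold
#: 8 clusters x 5 traps each.
DESIGN_RING_COUNTS = {
    "D170": {40: 6, 80: 12, 160: 24, 320: 48, 640: 40, 960: 40},
    "D200": {40: 24, 80: 24, 160: 24, 320: 48, 640: 40, 960: 40},
}

CLUSTER_RINGS_M = (640, 960)
N_CLUSTERS = 8
TRAPS_PER_CLUSTER = 5
CLUSTER_SPACING_M = 40.0  # chord spacing between traps within a cluster


@dataclass(frozen=True)
class Trap:
    trap_id: str
    x: float
    y: float
    ring_m: int

    @property
    def distance(self) -> float:
        return float(np.hypot(self.x, self.y))


@dataclass(frozen=True)
class TrapLayout:
    """Trap coordinates and ring membership for a named grid design."""

    design_id: str
    traps: tuple[Trap, ...]

    def __post_init__(self) -> None:
        counts = DESIGN_RING_COUNTS.get(self.design_id)
        if counts is not None:
            got = {r: sum(1 for t in self.traps if t.ring_m == r) for r in counts}
            if got != counts:
                raise ValueError(
                    f"{self.design_id}: ring counts {got} != expected {counts}"
                )

    def __len__(self) -> int:
        return len(self.traps)

    @property
    def ring_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for t in self.traps:
            out[t.ring_m] = out.get(t.ring_m, 0) + 1
        return dict(sorted(out.items()))

    def trap(self, trap_id: str) -> Trap:
        try:
            return self._index()[trap_id]
        except KeyError:
            raise KeyError(f"unknown trap_id {trap_id!r} in design {self.design_id}")

    def _index(self) -> dict[str, Trap]:
        idx = self.__dict__.get("_idx")
        if idx is None:
            idx = {t.trap_id: t for t in self.traps}
            self.__dict__["_idx"] = idx
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trap_id": [t.trap_id for t in self.traps],
                "design_id": self.design_id,
                "x_m": [t.x for t in self.traps],
                "y_m": [t.y for t in self.traps],
                "ring_m": [t.ring_m for t in self.traps],
            }
        )

    def coordinates(self) -> np.ndarray:
        """(n_traps, 2) array of x/y positions, trap order preserved."""
        return np.array([[t.x, t.y] for t in self.traps], dtype=float)


@dataclass(frozen=True)
class ReleaseEvent:
    """One replicate release of marked beetles from the grid centre."""

    release_id: int
    date: _date
    experience: str  # "experienced" | "naive"
    n_placed: int
    n_flew: int
    storage_days_min: int
    storage_days_max: int | None
    design_id: str
    retained: bool

    def __post_init__(self) -> None:
        if self.experience not in ("experienced", "naive"):
            raise ValueError(f"experience must be experienced|naive, got {self.experience!r}")
        if self.n_flew > self.n_placed:
            raise ValueError(
                f"release {self.release_id}: n_flew {self.n_flew} > n_placed {self.n_placed}"
            )


@dataclass(frozen=True)
class CaptureRecord:
    """Marked beetles recovered from one trap after one release."""

    release_id: int
    trap_id: str
    n_marked: int
    n_male: int = 0
    n_female: int = 0
    n_unknown: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_marked, self.n_male, self.n_female, self.n_unknown)
        if any(c < 0 for c in counts):
            raise ValueError("capture counts must be non-negative")
        if self.n_male + self.n_female + self.n_unknown != self.n_marked:
            raise ValueError(
                f"sex counts {self.n_male}+{self.n_female}+{self.n_unknown} "
                f"!= n_marked {self.n_marked}"
            )


@dataclass(frozen=True)
class RingSummary:
    """Recaptures summed over all traps of one ring for one release.

    ``pr_percent`` is the per-trap recapture rate expressed as a percentage
    of the beetles that flew: 100 * n_recaptured / (n_traps * n_flew).
    This percent scale matches the magnitude of the fitted diffusion scale
    parameters (A' ~ 2.5 predicts ~0.07 % per trap at 40 m).
    """

    release_id: int
    ring_m: int
    n_traps: int
    n_recaptured: int
    n_flew: int
    n_male: int = 0
    n_female: int = 0

    @property
    def pr_percent(self) -> float:
        return 100.0 * self.n_recaptured / (self.n_traps * self.n_flew)


@dataclass(frozen=True)
class MechanisticDecomposition:
    """User-supplied mechanistic rates behind the fitted trap-catch constants.

    The trap-catch curve's A and B are combinations of the trap effective
    sampling rate alpha (m^2/day), the diffusion rate D (m^2/day), the
    disappearance rate delta (1/day), and for the flat-tail model the local
    density rho of long-distance dispersers (per m^2).  (A, B) alone cannot
    identify the three rates — this record only carries values supplied by
    the user and the combinations they imply; nothing in the package
    estimates them.
    """

    alpha: float
    D: float
    delta: float
    rho: float = 0.0
    N0: int = 1

    @property
    def B(self) -> float:
        """Spatial scale of dispersal implied by the rates (m).

        Two renderings circulate for this combination: the square-root
        form sqrt(D/delta), dimensionally a length, and a plain ratio
        D/delta (an area).  The square-root form is used here; since B
        is always fitted as a free constant, nothing downstream depends
        on the choice (see docs/methods.md).
        """
        return float(np.sqrt(self.D / self.delta))

    @property
    def A_prime(self) -> float:
        """Release-normalized trap-catch scale implied by the rates.

        Rendered as alpha / (8 pi D^3 delta)^(1/4); like B, this
        combination is recorded for reference only and is never used in
        fitting, where A' is a free constant.
        """
        return float(self.alpha / (8.0 * np.pi * self.D**3 * self.delta) ** 0.25)

    @property
    def C(self) -> float:
        """Flat-tail per-trap catch, alpha * rho (beetles per trap)."""
        return self.alpha * self.rho

    @property
    def C_prime(self) -> float:
        return self.C / self.N0


# ---------------------------------------------------------------------------
# layout construction


def build_trap_layout(design_id: str) -> TrapLayout:
    """Construct the trap grid for a named design ("D170" or "D200").

    Full inner rings space traps equally in angle starting from due north,
    clockwise.  Outer rings hold 8 equally spaced clusters of 5 traps at
    40 m chord intervals along the ring, each cluster centred on its
    azimuth.  Pure function: repeated calls give identical layouts.
    """
    try:
        ring_counts = DESIGN_RING_COUNTS[design_id]
    except KeyError:
        raise ValueError(
            f"unknown design_id {design_id!r}; expected one of {sorted(DESIGN_RING_COUNTS)}"
        )

    traps: list[Trap] = []
    for ring, n in ring_counts.items():
        r = float(ring)
        if ring in CLUSTER_RINGS_M:
            azimuths = _cluster_azimuths(r)
        else:
            azimuths = np.arange(n) * (2 * np.pi / n)
        for k, az in enumerate(azimuths):
            # azimuth measured clockwise from north: x = r sin(az), y = r cos(az)
            traps.append(
                Trap(
                    trap_id=f"{design_id}-{ring}-{k + 1:02d}",
                    x=r * float(np.sin(az)),
                    y=r * float(np.cos(az)),
                    ring_m=ring,
                )
            )
    return TrapLayout(design_id=design_id, traps=tuple(traps))


def _cluster_azimuths(radius: float) -> np.ndarray:
    """Azimuths for 8 clusters of 5 traps at 40 m chord spacing."""
    step = 2.0 * np.arcsin(CLUSTER_SPACING_M / (2.0 * radius))  # chord -> angle
    centres = np.arange(N_CLUSTERS) * (2 * np.pi / N_CLUSTERS)
    offsets = (np.arange(TRAPS_PER_CLUSTER) - (TRAPS_PER_CLUSTER - 1) / 2.0) * step
    return (centres[:, None] + offsets[None, :]).ravel()


# ---------------------------------------------------------------------------
# ring aggregation


def aggregate_by_ring(
    captures: Iterable[CaptureRecord],
    layout: TrapLayout,
    releases: Iterable[ReleaseEvent],
) -> list[RingSummary]:
    """Sum recaptures over all traps of each ring, per retained release.

    Every retained release contributes one row per ring of its design,
    including rings with zero captures.  Discarded releases (``retained``
    False) are excluded, as are their captures.
    """
    releases = list(releases)
    rel_index = {rel.release_id: rel for rel in releases}
    ring_counts = layout.ring_counts

    acc: dict[tuple[int, int], list[int]] = {}
    for rel in releases:
        if rel.retained:
            for ring in ring_counts:
                acc[(rel.release_id, ring)] = [0, 0, 0]  # total, male, female

    for cap in captures:
        rel = rel_index.get(cap.release_id)
        if rel is None:
            raise ValueError(f"capture references unknown release_id {cap.release_id}")
        ring = layout.trap(cap.trap_id).ring_m  # KeyError with trap_id if missing
        if not rel.retained:
            continue
        cell = acc[(cap.release_id, ring)]
        cell[0] += cap.n_marked
        cell[1] += cap.n_male
        cell[2] += cap.n_female

    out = []
    for (rid, ring), (total, male, female) in sorted(acc.items()):
        out.append(
            RingSummary(
                release_id=rid,
                ring_m=ring,
                n_traps=ring_counts[ring],
                n_recaptured=total,
                n_flew=rel_index[rid].n_flew,
                n_male=male,
                n_female=female,
            )
        )
    return out


def ring_summary_frame(rows: Sequence[RingSummary]) -> pd.DataFrame:
    """Tabulate ring summaries (one row per release x ring)."""
    return pd.DataFrame(
        {
            "release_id": [r.release_id for r in rows],
            "ring_m": [r.ring_m for r in rows],
            "n_traps": [r.n_traps for r in rows],
            "n_recaptured": [r.n_recaptured for r in rows],
            "n_flew": [r.n_flew for r in rows],
            "n_male": [r.n_male for r in rows],
            "n_female": [r.n_female for r in rows],
            "pr_percent": [r.pr_percent for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# fixtures

_FIXTURES = ("table1_releases", "table3_diffusion_params", "design_D170", "design_D200")


def load_fixture(name: str) -> pd.DataFrame:
    """Return a packaged study table.

    ``table1_releases``
        the 15 replicate releases with flight/recapture counts and sex
        ratios; ``retained`` is 0 for the three discarded low-flight
        replicates.
    ``table3_diffusion_params``
        fitted diffusion-model parameters for all model x variance-function
        combinations, as printed (long format).
    ``design_D170`` / ``design_D200``
        the trap grids, as built by :func:`build_trap_layout`.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {_FIXTURES}")
    if name.startswith("design_"):
        return build_trap_layout(name.removeprefix("design_")).to_frame()
    path = importlib.resources.files("dispersalkit.fixtures") / f"{name}.csv"
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p)
    return df


def table1_release_events(only_retained: bool = False) -> list[ReleaseEvent]:
    """The packaged releases as :class:`ReleaseEvent` objects."""
    df = load_fixture("table1_releases")
    out = []
    for row in df.itertuples(index=False):
        ev = ReleaseEvent(
            release_id=int(row.release_id),
            date=_date.fromisoformat(row.date),
            experience=row.experience,
            n_placed=int(row.n_placed),
            n_flew=int(row.n_flew),
            storage_days_min=int(row.storage_days_min),
            storage_days_max=None if pd.isna(row.storage_days_max) else int(row.storage_days_max),
            design_id=row.design_id,
            retained=bool(row.retained),
        )
        if ev.retained or not only_retained:
            out.append(ev)
    return out


def heterogeneous_power_params() -> dict[str, float]:
    """Best-model parameter estimates (heterogeneous diffusion, power variance)."""
    df = load_fixture("table3_diffusion_params")
    sel = df[(df["model"] == "heterogeneous") & (df["variance"] == "power")]
    return dict(zip(sel["param"], sel["estimate"]))


# ---------------------------------------------------------------------------
# CSV interfaces (UTF-8, '.' decimal, headers required)


def write_traps_csv(layout: TrapLayout, path) -> None:
    layout.to_frame().to_csv(path, index=False)


def read_traps_csv(path) -> TrapLayout:
    df = pd.read_csv(path, float_precision="round_trip")
    design = df["design_id"].iloc[0]
    traps = tuple(
        Trap(trap_id=str(r.trap_id), x=float(r.x_m), y=float(r.y_m), ring_m=int(r.ring_m))
        for r in df.itertuples(index=False)
    )
    return TrapLayout(design_id=design, traps=traps)


def write_releases_csv(releases: Sequence[ReleaseEvent], path) -> None:
    pd.DataFrame(
        {
            "release_id": [r.release_id for r in releases],
            "date": [r.date.isoformat() for r in releases],
            "experience": [r.experience for r in releases],
            "n_placed": [r.n_placed for r in releases],
            "n_flew": [r.n_flew for r in releases],
            "storage_days_min": [r.storage_days_min for r in releases],
            "storage_days_max": [r.storage_days_max for r in releases],
            "design_id": [r.design_id for r in releases],
            "retained": [int(r.retained) for r in releases],
        }
    ).to_csv(path, index=False)


def read_releases_csv(path) -> list[ReleaseEvent]:
    df = pd.read_csv(path)
    return [
        ReleaseEvent(
            release_id=int(r.release_id),
            date=_date.fromisoformat(str(r.date)),
            experience=str(r.experience),
            n_placed=int(r.n_placed),
            n_flew=int(r.n_flew),
            storage_days_min=int(r.storage_days_min),
            storage_days_max=None if pd.isna(r.storage_days_max) else int(r.storage_days_max),
            design_id=str(r.design_id),
            retained=bool(int(r.retained)),
        )
        for r in df.itertuples(index=False)
    ]


def write_captures_csv(captures: Sequence[CaptureRecord], path) -> None:
    pd.DataFrame(
        {
            "release_id": [c.release_id for c in captures],
            "trap_id": [c.trap_id for c in captures],
            "n_marked": [c.n_marked for c in captures],
            "n_male": [c.n_male for c in captures],
            "n_female": [c.n_female for c in captures],
            "n_unknown": [c.n_unknown for c in captures],
        }
    ).to_csv(path, index=False)


def read_captures_csv(path) -> list[CaptureRecord]:
    df = pd.read_csv(path)
    return [
        CaptureRecord(
            release_id=int(r.release_id),
            trap_id=str(r.trap_id),
            n_marked=int(r.n_marked),
            n_male=int(r.n_male),
            n_female=int(r.n_female),
            n_unknown=int(r.n_unknown),
        )
        for r in df.itertuples(index=False)
    ]
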
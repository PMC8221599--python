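"""Run designs and aperture matrices for the two mapping paradigms.

The mapped dimension is expressed in normalized units ``u`` in ``[0, 1]``:
``u = 0`` is the top of the mapped space (5 d.v.a. above fixation for
spatial mapping; the hairline for face-part mapping) and ``u = 1`` the
bottom (5 d.v.a. below fixation; the chin).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RunDesign",
    "ApertureMatrix",
    "make_run_design",
    "build_aperture",
    "norm_to_dva",
    "dva_to_norm",
]

TRIAL_SEQUENCE = ("down", "up", "blank", "up", "down", "blank")

#: Total mapped extent in degrees of visual angle (spatial condition).
SPACE_EXTENT_DVA = 10.0


@dataclass(frozen=True)
class RunDesign:
    """Timing and stimulus geometry of one mapping run."""

    kind: str
    tr: float = 1.0
    trial_sequence: tuple[str, ...] = TRIAL_SEQUENCE
    trial_duration: float = 32.0
    n_dummy: int = 10
    refresh_rate: float = 60.0
    frames_on: int = 5
    frames_off: int = 5
    aperture_height: float = 0.11
    step_size: float = 0.055
    update_period: int = 2  # TRs per aperture position
    space_edges: tuple[str, str] = ("5 dva above fixation", "5 dva below fixation")

    def __post_init__(self) -> None:
        if self.kind not in ("spatial", "face"):
            raise ValueError(f"unknown design kind: {self.kind!r}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if not (0 < self.aperture_height < 1):
            raise ValueError("aperture_height must lie in (0, 1)")
        if not (0 < self.step_size < 1):
            raise ValueError("step_size must lie in (0, 1)")
        if tuple(self.trial_sequence) != TRIAL_SEQUENCE:
            raise ValueError(f"trial_sequence must be {TRIAL_SEQUENCE}")

    @property
    def n_trials(self) -> int:
        return len(self.trial_sequence)

    @property
    def active_duration(self) -> float:
        return self.n_trials * self.trial_duration

    @property
    def n_active_volumes(self) -> int:
        return int(round(self.active_duration / self.tr))

    @property
    def total_volumes(self) -> int:
        return self.n_dummy + self.n_active_volumes

    @property
    def volumes_per_trial(self) -> int:
        return int(round(self.trial_duration / self.tr))

    @property
    def flicker_hz(self) -> float:
        """Identity-cycling frequency implied by the ON/OFF frame counts."""
        return self.refresh_rate / (self.frames_on + self.frames_off)

    @property
    def n_positions(self) -> int:
        """Aperture positions per sweep trial (position held ``update_period`` TRs)."""
        return self.volumes_per_trial // self.update_period

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trial_sequence"] = list(d["trial_sequence"])
        d["space_edges"] = list(d["space_edges"])
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RunDesign":
        d = dict(d)
        if "trial_sequence" in d:
            d["trial_sequence"] = tuple(d["trial_sequence"])
        if "space_edges" in d:
            d["space_edges"] = tuple(d["space_edges"])
        return cls(**d)


_CANONICAL = {
    "spatial": dict(
        aperture_height=0.11,  # bar height 1.1 dva on a 10 dva space
        step_size=0.055,  # 0.55 dva per update
        space_edges=("5 dva above fixation", "5 dva below fixation"),
    ),
    "face": dict(
        aperture_height=1.0 / 9.0,  # sampling window one-ninth of the face
        step_size=1.0 / 18.0,  # one-eighteenth of the face per update
        space_edges=("hairline", "chin"),
    ),
}


def make_run_design(kind: str, **overrides) -> RunDesign:
    """Return the canonical :class:`RunDesign` for ``kind`` with optional overrides.

    Parameters
    ----------
    kind : {'spatial', 'face'}
    **overrides
        Any declared :class:`RunDesign` field.
    """
    if kind not in _CANONICAL:
        raise ValueError(f"unknown design kind: {kind!r}")
    fields = {f.name for f in dataclasses.fields(RunDesign)}
    bad = set(overrides) - fields
    if bad:
        raise ValueError(f"unknown design fields: {sorted(bad)}")
    params = dict(_CANONICAL[kind])
    params.update(overrides)
    return RunDesign(kind=kind, **params)


@dataclass
class ApertureMatrix:
    """Time x stimulus-space occupancy of the mapping aperture.

    ``weights[t, b]`` is the fraction of bin ``b`` covered by the aperture
    at active volume ``t`` (dummy volumes excluded). Blank-trial rows are
    all zero.
    """

    weights: np.ndarray
    bin_centers: np.ndarray
    kind: str
    active_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_bins(self) -> int:
        return self.weights.shape[1]

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


def _sweep_positions(design: RunDesign) -> np.ndarray:
    """Top edge of the aperture at each update of a down sweep."""
    return np.arange(design.n_positions) * design.step_size


def _interval_occupancy(lo: float, hi: float, edges: np.ndarray) -> np.ndarray:
    """Fractional coverage of each bin by the interval [lo, hi]."""
    width = edges[1] - edges[0]
    overlap = np.minimum(hi, edges[1:]) - np.maximum(lo, edges[:-1])
    occ = np.clip(overlap, 0.0, None) / width
    occ[occ < 1e-9] = 0.0  # drop float slivers when edges align with bins
    return occ


def build_aperture(design: RunDesign, n_bins: int = 200) -> ApertureMatrix:
    """Build the aperture occupancy matrix for a run design.

    The down sweep starts with the aperture flush with the top of the space
    (top edge at ``u = 0``) and steps toward the bottom by ``step_size``
    every ``update_period`` TRs; the up sweep is the exact time reversal of
    the down sweep's position schedule. Edge bins carry fractional
    occupancy computed by analytic interval overlap.
    """
    if n_bins < 20:
        raise ValueError("n_bins must be at least 20")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_width = 1.0 / n_bins
    if design.aperture_height < 2 * bin_width:
        raise ValueError(
            f"n_bins={n_bins} too coarse: aperture spans fewer than 2 bins"
        )
    centers = 0.5 * (edges[:-1] + edges[1:])

    tops = _sweep_positions(design)
    v_trial = design.volumes_per_trial
    rows_down = np.zeros((v_trial, n_bins))
    for i, top in enumerate(tops):
        occ = _interval_occupancy(top, top + design.aperture_height, edges)
        for rep in range(design.update_period):
            t = i * design.update_period + rep
            if t < v_trial:
                rows_down[t] = occ
    rows_up = rows_down[::-1].copy()
    blank = np.zeros((v_trial, n_bins))

    parts = {"down": rows_down, "up": rows_up, "blank": blank}
    weights = np.vstack([parts[label] for label in design.trial_sequence])
    active_mask = np.concatenate(
        [np.full(v_trial, label != "blank") for label in design.trial_sequence]
    )
    return ApertureMatrix(
        weights=weights, bin_centers=centers, kind=design.kind, active_mask=active_mask
    )


def norm_to_dva(u):
    """Normalized elevation ``u`` to degrees of visual angle (positive = above fixation)."""
    return 5.0 - SPACE_EXTENT_DVA * np.asarray(u, dtype=float)


def dva_to_norm(dva):
    """Inverse of :func:`norm_to_dva`."""
    return (5.0 - np.asarray(dva, dtype=float)) / SPACE_EXTENT_DVA
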
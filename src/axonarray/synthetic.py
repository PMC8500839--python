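"""Synthetic ground-truth data for every stage of the pipeline.

Each generator is a pure function of its config (seed included): rerunning
with the same config reproduces the output byte for byte.  Every generator
also returns a machine-readable ground-truth record so the downstream module
can be scored on recovery.  Random streams are split per purpose from the
config seed with ``numpy.random.SeedSequence`` so adding a stream does not
perturb the others.

The array generator emulates the ATPγS titration that motivates the
fall-off model: an apo population of contiguous-array OAD counts (the study
counted n = 319/180/214/222/159 arrays at 0/10/30/100/1,000 μM) is run
under a known model and alpha down to per-condition target coverages, and
the observed tables are per-condition samples of the surviving arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .falloff import (
    ArrayPopulation,
    ConditionTable,
    FallOffModel,
    coverage as _coverage,
    simulate_lengths_to_coverage,
)
from .geometry import LatticeModel, PointSet
from .gliding import Track
from .lcid import (
    DEFAULT_SIZE_CLASSES,
    DensityPattern,
    SizeClassMap,
    best_window_score,
    classify_residues,
)
from .micrograph import Micrograph, RectangleMask

__all__ = [
    "SyntheticArrayConfig",
    "ArrayObservationSet",
    "make_array_observations",
    "SyntheticProteomeConfig",
    "make_proteome",
    "SyntheticLatticeConfig",
    "make_lattice",
    "SyntheticImageConfig",
    "make_filament_image",
    "SyntheticTrackConfig",
    "make_tracks",
]

# study sample sizes: arrays counted per ATPγS condition (0/10/30/100/1000 μM)
STUDY_N_ARRAYS = (319, 180, 214, 222, 159)
STUDY_CONDITION_LABELS = ("0", "10", "30", "100", "1000")
# per-condition coverage targets; the titration data are shown graphically,
# so these are a stand-in depletion series, not the study's values
DEFAULT_TARGET_COVERAGES = (1.0, 0.8, 0.6, 0.4, 0.15)


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# (a) OAD array populations


@dataclass(frozen=True)
class SyntheticArrayConfig:
    n_arrays_per_condition: tuple[int, ...] = STUDY_N_ARRAYS
    condition_labels: tuple[str, ...] = STUDY_CONDITION_LABELS
    initial_length_sampler: dict = field(
        default_factory=lambda: {
            "name": "truncated_geometric",
            "p": 0.125,
            "low": 1,
            "high": 60,
        }
    )
    true_model: FallOffModel = FallOffModel.END_RELEASE
    true_alpha: float = 0.1
    target_coverages: tuple[float, ...] = DEFAULT_TARGET_COVERAGES
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.n_arrays_per_condition)
        if not (n == len(self.condition_labels) == len(self.target_coverages)):
            raise ValueError("condition lists must have equal length")
        if any(k < 1 for k in self.n_arrays_per_condition):
            raise ValueError("array counts must be positive")
        cov = self.target_coverages
        if any(c <= 0 or c > 1 for c in cov):
            raise ValueError("coverages must lie in (0, 1]")
        if any(b > a + 1e-12 for a, b in zip(cov, cov[1:])):
            raise ValueError("coverages must be non-increasing across conditions")
        if cov[0] > 1.0:
            raise ValueError("unreachable coverage: first condition exceeds apo")
        if not 0.0 <= self.true_alpha <= 1.0:
            raise ValueError("true_alpha must lie in [0, 1]")


def _sample_lengths(spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    name = spec.get("name")
    if name == "truncated_geometric":
        low, high = int(spec.get("low", 1)), int(spec.get("high", 60))
        p = float(spec["p"])
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = rng.geometric(p, size=2 * (n - filled))
            draw = draw[(draw >= low) & (draw <= high)]
            take = min(len(draw), n - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
        return out
    if name == "uniform_int":
        return rng.integers(int(spec["low"]), int(spec["high"]) + 1, size=n)
    if name == "constant":
        return np.full(n, int(spec["value"]), dtype=np.int64)
    raise ValueError(f"unknown length sampler {name!r}")


@dataclass
class ArrayObservationSet:
    """Observed per-condition tables plus the ground truth that made them."""

    table: pd.DataFrame  # condition, array_id, n_oads
    conditions: list[ConditionTable]  # observed lengths + true pool coverage
    reference: ArrayPopulation  # the full apo pool (condition 0)
    ground_truth: dict


def make_array_observations(config: SyntheticArrayConfig) -> ArrayObservationSet:
    """Per-condition array-length tables from a known fall-off process.

    Condition 0 is the apo draw from the length sampler and defines the
    reference total.  Each later condition runs the configured true model
    from the full apo pool down to its target coverage; the observed table
    samples min(n_condition, survivors) arrays without replacement, the way
    a negative-stain image samples the reaction.
    """
    rngs = _rng_children(config.seed, 1 + 2 * (len(config.condition_labels) - 1))
    apo_lengths = _sample_lengths(
        config.initial_length_sampler, config.n_arrays_per_condition[0], rngs[0]
    )
    reference = ArrayPopulation.from_lengths(apo_lengths)

    rows = []
    conditions: list[ConditionTable] = []
    true_coverages = []
    for i, label in enumerate(config.condition_labels):
        if i == 0:
            observed = np.sort(apo_lengths)
            cov = 1.0
        else:
            rng_sim, rng_pick = rngs[2 * i - 1], rngs[2 * i]
            survivors = simulate_lengths_to_coverage(
                reference,
                config.true_model,
                config.true_alpha,
                config.target_coverages[i],
                rng_sim,
            )
            cov = survivors.sum() / reference.reference_total
            n_obs = min(config.n_arrays_per_condition[i], survivors.size)
            observed = np.sort(
                rng_pick.choice(survivors, size=n_obs, replace=False)
            )
        true_coverages.append(float(cov))
        conditions.append(
            ConditionTable(label=label, lengths=observed, coverage=float(cov))
        )
        for j, n_oads in enumerate(observed):
            rows.append(
                {"condition": label, "array_id": f"{label}_{j:04d}", "n_oads": int(n_oads)}
            )

    table = pd.DataFrame(rows, columns=["condition", "array_id", "n_oads"])
    ground_truth = {
        "model": FallOffModel(config.true_model).value,
        "alpha": config.true_alpha,
        "target_coverages": list(config.target_coverages),
        "true_coverages": true_coverages,
        "reference_total": reference.reference_total,
        "seed": config.seed,
    }
    return ArrayObservationSet(
        table=table, conditions=conditions, reference=reference, ground_truth=ground_truth
    )


# ---------------------------------------------------------------------------
# (b) proteomes with a planted pattern target and controlled decoys


@dataclass(frozen=True)
class SyntheticProteomeConfig:
    pattern_length: int = 18
    n_decoys: int = 4
    decoy_mismatch_counts: tuple[int, ...] = (1, 2, 3, 5)
    sequence_length_range: tuple[int, int] = (80, 160)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern_length < 1:
            raise ValueError("pattern_length must be positive")
        if len(self.decoy_mismatch_counts) != self.n_decoys:
            raise ValueError("decoy_mismatch_counts length must equal n_decoys")
        if any(k > self.pattern_length for k in self.decoy_mismatch_counts):
            raise ValueError("mismatch count exceeds pattern length")
        lo, hi = self.sequence_length_range
        if lo < self.pattern_length or hi < lo:
            raise ValueError("sequence_length_range must fit the pattern")


_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_RESIDUES, size=n))


def _mutate_to_other_class(
    residue: str, rng: np.random.Generator, size_map: SizeClassMap
) -> str:
    own = size_map.classes[residue]
    other_classes = [c for c in "LMSG" if c != own]
    cls = other_classes[int(rng.integers(len(other_classes)))]
    members = size_map.residues_of(cls)
    return members[int(rng.integers(len(members)))]


def _plant(
    window: str,
    pattern: DensityPattern,
    rng: np.random.Generator,
    length: int,
    want_penalty: int,
    size_map: SizeClassMap,
    max_tries: int = 200,
) -> tuple[str, int]:
    """Embed ``window`` in random flanks so its placement is the unique best."""
    for _ in range(max_tries):
        offset = int(rng.integers(0, length - len(window) + 1))
        seq = (
            _random_sequence(offset, rng)
            + window
            + _random_sequence(length - offset - len(window), rng)
        )
        score = best_window_score("tmp", seq, pattern, size_map)
        if score.penalty == want_penalty and score.offset == offset:
            # unique minimum: no other offset may tie
            ties = sum(
                1
                for off in range(len(seq) - len(pattern) + 1)
                if off != offset
                and _window_penalty(seq, off, pattern, size_map) <= want_penalty
            )
            if ties == 0:
                return seq, offset
    raise RuntimeError("could not plant a uniquely scoring window; widen the config")


def _window_penalty(seq: str, off: int, pattern: DensityPattern, size_map) -> int:
    from .lcid import penalty_score

    return penalty_score(seq, off, pattern, size_map)


def make_proteome(
    config: SyntheticProteomeConfig,
    size_map: SizeClassMap = DEFAULT_SIZE_CLASSES,
) -> tuple[list[SeqRecord], DensityPattern, pd.DataFrame]:
    """FASTA records with one penalty-0 target and decoys of known penalties.

    The density pattern is the size-class string of the planted target
    window; decoy k carries exactly its configured number of class-changing
    mismatches, and the construction verifies that each record's best window
    is the planted one, uniquely.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    lo, hi = config.sequence_length_range

    target_window = _random_sequence(config.pattern_length, rng)
    pattern = DensityPattern(classify_residues(target_window, size_map))

    records: list[SeqRecord] = []
    rows = []
    tgt_len = int(rng.integers(lo, hi + 1))
    tgt_seq, tgt_off = _plant(target_window, pattern, rng, tgt_len, 0, size_map)
    records.append(SeqRecord(Seq(tgt_seq), id="target_0", description="planted target"))
    rows.append(
        {"record_id": "target_0", "role": "target", "planted_offset": tgt_off,
         "true_penalty": 0}
    )

    for d, k in enumerate(config.decoy_mismatch_counts):
        window = list(target_window)
        positions = rng.choice(config.pattern_length, size=k, replace=False)
        for p in positions:
            window[p] = _mutate_to_other_class(window[p], rng, size_map)
        dec_len = int(rng.integers(lo, hi + 1))
        dec_seq, dec_off = _plant("".join(window), pattern, rng, dec_len, int(k), size_map)
        rid = f"decoy_{d}"
        records.append(SeqRecord(Seq(dec_seq), id=rid, description=f"decoy penalty {k}"))
        rows.append(
            {"record_id": rid, "role": "decoy", "planted_offset": dec_off,
             "true_penalty": int(k)}
        )

    truth = pd.DataFrame(rows, columns=["record_id", "role", "planted_offset", "true_penalty"])
    return records, pattern, truth


# ---------------------------------------------------------------------------
# (c) tubulin-dimer lattices with planted inter-PF angles


@dataclass(frozen=True)
class SyntheticLatticeConfig:
    n_protofilaments: int = 4
    inter_pf_angles_deg: tuple[float, ...] = (30.0, 25.0, 35.0)
    axial_rise_nm: float = 8.0
    n_repeats: int = 6
    coordinate_noise_sd_A: float = 0.0
    closed: bool = False
    radius_A: float = 120.0
    n_points_per_dimer: int = 60
    point_spread_A: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_protofilaments < 2:
            raise ValueError("need at least two protofilaments")
        expected = self.n_protofilaments if self.closed else self.n_protofilaments - 1
        if len(self.inter_pf_angles_deg) != expected:
            raise ValueError(
                f"expected {expected} inter-PF angles for "
                f"{'closed' if self.closed else 'open'} lattice"
            )
        if self.closed and abs(sum(self.inter_pf_angles_deg) - 360.0) > 1e-6:
            raise ValueError("closed lattice requires planted angles summing to 360°")
        if self.n_repeats < 3:
            raise ValueError("need at least three repeats")
        if self.coordinate_noise_sd_A < 0:
            raise ValueError("noise sd must be non-negative")


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_lattice(config: SyntheticLatticeConfig) -> tuple[LatticeModel, pd.DataFrame]:
    """Cylindrical lattice of rigid dimer copies with planted rotations.

    Adjacent protofilaments are related by a rotation about the lattice (z)
    axis by the planted lateral angle; successive repeats along one PF are
    pure translations by the axial rise.  Gaussian coordinate noise is added
    per atom after placement.
    """
    rng_ref, rng_noise = _rng_children(config.seed, 2)
    reference = rng_ref.normal(scale=config.point_spread_A, size=(config.n_points_per_dimer, 3))
    base = reference + np.array([config.radius_A, 0.0, 0.0])

    cum = np.concatenate([[0.0], np.cumsum(config.inter_pf_angles_deg)])
    rise_A = config.axial_rise_nm * 10.0
    dimers: dict[tuple[int, int], PointSet] = {}
    for pf in range(config.n_protofilaments):
        R = _rot_z(cum[pf])
        for rep in range(config.n_repeats):
            coords = base @ R.T + np.array([0.0, 0.0, rep * rise_A])
            if config.coordinate_noise_sd_A > 0:
                coords = coords + rng_noise.normal(
                    scale=config.coordinate_noise_sd_A, size=coords.shape
                )
            dimers[(pf, rep)] = PointSet(label=f"pf{pf}_rep{rep}", coordinates=coords)

    lattice = LatticeModel(
        dimers=dimers,
        reference_dimer=PointSet(label="reference", coordinates=reference),
        closed=config.closed,
    )
    pairs = [(i, i + 1) for i in range(config.n_protofilaments - 1)]
    if config.closed:
        pairs.append((config.n_protofilaments - 1, 0))
    truth = pd.DataFrame(
        {
            "pf_a": [a for a, _ in pairs],
            "pf_b": [b for _, b in pairs],
            "angle_deg": list(config.inter_pf_angles_deg),
        }
    )
    return lattice, truth


# ---------------------------------------------------------------------------
# (d) straight-filament phantom images


@dataclass(frozen=True)
class SyntheticImageConfig:
    image_shape_px: tuple[int, int] = (256, 256)
    pixel_size_A: float = 10.0
    filament_point_px: tuple[float, float] = (128.0, 128.0)
    filament_angle_deg: float = 0.0
    filament_width_px: float = 12.0
    filament_amplitude: float = 1.0
    particle_positions_px: tuple[tuple[float, float], ...] = ()
    particle_amplitude: float = 0.5
    particle_sigma_px: float = 3.0
    noise_sd: float = 0.0
    mask_width_factor: float = 1.5
    mask_soft_edge_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_shape_px) < 16:
            raise ValueError("image must be at least 16x16")
        if self.filament_width_px <= 0:
            raise ValueError("filament width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def make_filament_image(
    config: SyntheticImageConfig,
) -> tuple[Micrograph, RectangleMask, pd.DataFrame]:
    """Geometric filament phantom plus its rectangle mask and particle truth.

    The filament is a Gaussian ridge (sigma = width/2), translation-invariant
    along its axis; particles are Gaussian blobs.  The mask follows the
    filament axis across the whole image at ``mask_width_factor`` times the
    filament width ("slightly wider").  With noise_sd = 0 the image is a
    deterministic function of the config.
    """
    (rng_noise,) = _rng_children(config.seed, 1)
    h, w = config.image_shape_px
    ys, xs = np.mgrid[0:h, 0:w]
    theta = np.radians(config.filament_angle_deg)
    u = np.array([np.cos(theta), np.sin(theta)])
    v = np.array([-u[1], u[0]])
    x0, y0 = config.filament_point_px
    vv = (xs - x0) * v[0] + (ys - y0) * v[1]
    sigma = config.filament_width_px / 2.0
    img = config.filament_amplitude * np.exp(-(vv**2) / (2.0 * sigma**2))

    for px, py in config.particle_positions_px:
        r2 = (xs - px) ** 2 + (ys - py) ** 2
        img = img + config.particle_amplitude * np.exp(
            -r2 / (2.0 * config.particle_sigma_px**2)
        )
    if config.noise_sd > 0:
        img = img + rng_noise.normal(scale=config.noise_sd, size=img.shape)

    span = float(np.hypot(h, w)) + 2.0
    start = (x0 - span * u[0], y0 - span * u[1])
    end = (x0 + span * u[0], y0 + span * u[1])
    mask = RectangleMask(
        start=start,
        end=end,
        width_px=config.mask_width_factor * config.filament_width_px,
        soft_edge_px=config.mask_soft_edge_px,
    )
    truth = pd.DataFrame(
        [{"x_px": p[0], "y_px": p[1]} for p in config.particle_positions_px],
        columns=["x_px", "y_px"],
    )
    return Micrograph(pixels=img, pixel_size_A=config.pixel_size_A), mask, truth


# ---------------------------------------------------------------------------
# (e) gliding tracks


@dataclass(frozen=True)
class SyntheticTrackConfig:
    n_mobile: int = 20
    velocities_um_s: tuple[float, ...] = (3.0,)
    n_immobile: int = 3
    n_short: int = 2
    frame_rate_hz: float = 13.5
    duration_s_range: tuple[float, float] = (2.0, 8.0)
    position_noise_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mobile < 0 or self.n_immobile < 0 or self.n_short < 0:
            raise ValueError("track counts must be non-negative")
        if self.n_mobile > 0 and not self.velocities_um_s:
            raise ValueError("mobile tracks need planted velocities")
        if any(v <= 0 for v in self.velocities_um_s):
            raise ValueError("planted velocities must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")
        lo, hi = self.duration_s_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid duration range")


def _make_one_track(
    track_id: str,
    velocity: float,
    duration: float,
    rng: np.random.Generator,
    frame_rate: float,
    noise: float,
) -> Track:
    n_frames = max(int(np.floor(duration * frame_rate)) + 1, 2)
    t = np.arange(n_frames) / frame_rate
    angle = rng.uniform(0, 2 * np.pi)
    start = rng.uniform(0, 50, size=2)
    x = start[0] + velocity * t * np.cos(angle)
    y = start[1] + velocity * t * np.sin(angle)
    if noise > 0:
        x = x + rng.normal(scale=noise, size=n_frames)
        y = y + rng.normal(scale=noise, size=n_frames)
    return Track(track_id=track_id, times_s=t, x_um=x, y_um=y, frame_rate_hz=frame_rate)


def make_tracks(config: SyntheticTrackConfig) -> tuple[list[Track], pd.DataFrame]:
    """Straight mobile tracks plus immobile and sub-1-s nuisance tracks.

    Mobile tracks move at their planted speed along a random direction with
    isotropic Gaussian position noise; immobile tracks jitter around a fixed
    point; short tracks last strictly less than 1 s so the duration filter
    removes them.
    """
    (rng,) = _rng_children(config.seed, 1)
    tracks: list[Track] = []
    rows = []

    for i in range(config.n_mobile):
        v = config.velocities_um_s[i % len(config.velocities_um_s)]
        duration = rng.uniform(*config.duration_s_range)
        tid = f"mobile_{i:03d}"
        tracks.append(
            _make_one_track(tid, v, duration, rng, config.frame_rate_hz,
                            config.position_noise_um)
        )
        rows.append({"track_id": tid, "kind": "mobile", "velocity_um_s": v,
                     "duration_s": duration})

    for i in range(config.n_immobile):
        duration = rng.uniform(*config.duration_s_range)
        n_frames = max(int(np.floor(duration * config.frame_rate_hz)) + 1, 2)
        t = np.arange(n_frames) / config.frame_rate_hz
        start = rng.uniform(0, 50, size=2)
        noise = config.position_noise_um
        x = np.full(n_frames, start[0])
        y = np.full(n_frames, start[1])
        if noise > 0:
            x = x + rng.normal(scale=noise, size=n_frames)
            y = y + rng.normal(scale=noise, size=n_frames)
        tid = f"immobile_{i:03d}"
        tracks.append(Track(tid, t, x, y, config.frame_rate_hz))
        rows.append({"track_id": tid, "kind": "immobile", "velocity_um_s": 0.0,
                     "duration_s": duration})

    for i in range(config.n_short):
        v = config.velocities_um_s[0] if config.velocities_um_s else 0.5
        duration = rng.uniform(0.3, 0.95)
        tid = f"short_{i:03d}"
        tracks.append(
            _make_one_track(tid, v, duration, rng, config.frame_rate_hz,
                            config.position_noise_um)
        )
        rows.append({"track_id": tid, "kind": "short", "velocity_um_s": v,
                     "duration_s": duration})

    truth = pd.DataFrame(rows, columns=["track_id", "kind", "velocity_um_s", "duration_s"])
    return tracks, truth
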
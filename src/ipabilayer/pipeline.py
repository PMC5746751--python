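"""End-to-end analysis pipeline and convergence diagnostics.

``run_pipeline`` takes a configuration (a loaded trajectory or a synthetic
spec), restricts to the analysis time window (by default the final 25% of
frames, mirroring the practice of analyzing the tail of an equilibrated run),
computes all structural and mechanical observables, classifies the system
against the phase thresholds, and writes TSV/JSON reports.  A block-average
convergence check flags drift between the first and last block means.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import mechanical, structural
from .constants import DEFAULT_TEMPERATURE
from .model import Trajectory, load_trajectory
from .phase import PhaseCall, PropertyRecord, Thresholds, classify_record
from .synthetic import SyntheticSpec, generate_trajectory

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs; CLI flags override file values."""

    coord_path: str | None = None
    traj_path: str | None = None
    topology_path: str | None = None
    synthetic: SyntheticSpec | None = None
    temperature: float = DEFAULT_TEMPERATURE
    tilt_bin_width: float = 1.0  # degrees
    density_bin_width: float = 0.05  # nm
    splay_cutoff: float = 1.0  # nm
    window_rt_multiple: float = 2.0
    analysis_fraction: float = 0.25  # final fraction of frames analyzed
    thresholds: Thresholds = field(default_factory=Thresholds)
    convergence_blocks: int = 5
    compute_splay: bool = True
    output_dir: str | None = None

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 < self.analysis_fraction <= 1.0:
            raise ValueError("analysis_fraction must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "thresholds" in data:
            data["thresholds"] = Thresholds(**data["thresholds"])
        if "synthetic" in data:
            from .model import IPAComposition

            syn = data["synthetic"]
            if "composition" in syn:
                syn["composition"] = IPAComposition(**syn["composition"])
            data["synthetic"] = SyntheticSpec(**syn)
        return cls(**data)


@dataclass
class ConvergenceReport:
    """Block means and standard errors per observable; drift flags."""

    block_means: dict[str, list[float]]
    block_sems: dict[str, list[float]]
    drift: dict[str, bool]
    n_blocks: int

    @property
    def any_drift(self) -> bool:
        return any(self.drift.values())


def convergence_check(
    series: dict[str, np.ndarray] | np.ndarray, k_blocks: int = 5
) -> ConvergenceReport:
    """Split each series into k equal blocks; flag first-vs-last drift.

    Drift is flagged when the first and last block means differ by more than
    twice the pooled standard error — a cheap stationarity screen analogous
    to verifying equilibration by property convergence.
    """
    if k_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if isinstance(series, np.ndarray):
        series = {"series": series}
    means: dict[str, list[float]] = {}
    sems: dict[str, list[float]] = {}
    drift: dict[str, bool] = {}
    for name, values in series.items():
        values = np.asarray(values, dtype=float)
        if values.size < 2 * k_blocks:
            raise ValueError(
                f"series {name!r} too short ({values.size}) for {k_blocks} blocks"
            )
        blocks = np.array_split(values, k_blocks)
        m = [float(b.mean()) for b in blocks]
        s = [float(b.std(ddof=1) / math.sqrt(len(b))) for b in blocks]
        means[name], sems[name] = m, s
        pooled = math.sqrt(s[0] ** 2 + s[-1] ** 2)
        drift[name] = abs(m[0] - m[-1]) > 2.0 * pooled if pooled > 0 else m[0] != m[-1]
    return ConvergenceReport(means, sems, drift, k_blocks)


def _resolve_trajectory(config: AnalysisConfig) -> Trajectory:
    if config.synthetic is not None:
        traj, _ = generate_trajectory(config.synthetic)
        return traj
    if config.coord_path is None or config.topology_path is None:
        raise ValueError(
            "config must provide either a synthetic spec or coordinate + "
            "topology paths"
        )
    return load_trajectory(config.coord_path, config.traj_path, config.topology_path)


def run_pipeline(
    config: AnalysisConfig, traj: Trajectory | None = None
) -> tuple[PropertyRecord, PhaseCall, ConvergenceReport]:
    """Generate/load -> structural -> mechanical -> classify -> report."""

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    t0 = stage("input")
    if traj is None:
        traj = _resolve_trajectory(config)
    n_skip = int(len(traj) * (1.0 - config.analysis_fraction))
    window = traj.sliced(n_skip) if n_skip else traj
    logger.info(
        "analyzing %d/%d frames (final %.0f%%), %.2fs",
        len(window), len(traj), 100 * config.analysis_fraction,
        time.perf_counter() - t0,
    )

    t0 = stage("structural")
    series = structural.area_series(window)
    a_ipa = structural.area_per_ipa(series)
    scd_maps = {}
    gauche_maps = {}
    for ct in ("cation", "anion"):
        scd = structural.scd_profile(window, ct)
        scd_maps[ct] = {c: abs(v) for c, v in scd.as_mapping().items()}
        gauche_maps[ct] = structural.gauche_fractions(window, ct).as_mapping()
    abs_scd = structural.middle_segment_average(scd_maps, window.composition)
    gauche = structural.middle_segment_average(gauche_maps, window.composition)
    tilts = structural.tilt_angles(window)
    logger.info("structural done, %.2fs", time.perf_counter() - t0)

    t0 = stage("mechanical")
    ka = mechanical.area_expansion_modulus(series, config.temperature)
    chi_by_chain = {}
    for ct in ("cation", "anion"):
        fit = mechanical.tilt_modulus_from_samples(
            tilts[ct], config.temperature, config.tilt_bin_width,
            config.window_rt_multiple,
        )
        chi_by_chain[ct] = fit.chi
    pooled_fit = mechanical.tilt_modulus_from_samples(
        tilts.pooled(), config.temperature, config.tilt_bin_width,
        config.window_rt_multiple,
    )
    kc_eff = None
    splay_result = None
    if config.compute_splay:
        splay = mechanical.splay_angles(window, config.splay_cutoff)
        splay_result = mechanical.splay_modulus(
            splay, config.temperature, config.tilt_bin_width,
            config.window_rt_multiple,
        )
        if splay_result.chi and all(c > 0 for c in splay_result.chi.values()):
            kc_eff = mechanical.effective_bending_rigidity(
                splay_result.chi, splay_result.phi
            )
    logger.info("mechanical done, %.2fs", time.perf_counter() - t0)

    record = PropertyRecord(
        composition=window.composition,
        a_ipa=a_ipa,
        k_a=ka,
        chi_tilt=pooled_fit.chi,
        kc_eff=kc_eff,
        abs_scd=abs_scd,
        gauche=gauche,
    )
    call = classify_record(record, config.thresholds)

    k = min(config.convergence_blocks, len(series.values) // 2)
    if k >= 2:
        conv = convergence_check({"lateral_area": series.values}, k)
    else:
        logger.warning("trajectory too short for block averaging; skipping")
        conv = ConvergenceReport({}, {}, {}, 0)

    if config.output_dir:
        _write_outputs(config, record, call, conv, pooled_fit, tilts)
    return record, call, conv


def _record_to_dict(record: PropertyRecord) -> dict:
    d = {
        "composition": {
            "m": record.composition.m,
            "n": record.composition.n,
            "abbreviation": record.composition.abbreviation,
            "delta_c": record.composition.delta_c,
            "total_carbons": record.composition.total_carbons,
        }
    }
    for name in ("a_ipa", "k_a", "chi_tilt", "kc_eff", "abs_scd", "gauche"):
        value = getattr(record, name)
        d[name] = value if value is not None else None
        if value is None:
            d[f"{name}_missing_reason"] = "not computed"
    return d


def _write_outputs(config, record, call, conv, pooled_fit, tilts) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "record": _record_to_dict(record),
        "phase": {
            "votes": call.votes,
            "overall": call.overall,
            "tally": list(call.tally),
            "rule_expected": call.rule_expected,
        },
        "tilt_fit": dataclasses.asdict(pooled_fit),
        "convergence": {
            "block_means": conv.block_means,
            "drift": conv.drift,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    dist = structural.tilt_distribution(tilts.pooled(), config.tilt_bin_width)
    np.savetxt(
        outdir / "tilt_distribution.tsv",
        np.column_stack([dist.bin_centers, dist.probabilities]),
        header="theta_deg\tprobability", delimiter="\t", comments="",
    )
    logger.info("wrote report to %s", outdir)
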
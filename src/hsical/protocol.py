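"""Protocol orchestration: calibrate -> characterize -> aberrations -> verify.

The stages run strictly in that order; a stage never runs before its
prerequisites are done, and a failed prerequisite halts its dependents while
the partial report is still written.  Every stochastic stage records its
seed; identical config + seed reproduce an identical report (modulo the
timestamp field).

All thresholds live in the configuration with the protocol's defaults:
Michelson contrast 0.1, line-match tolerance 1.5 nm, reflectance clip 1.5,
warm-up criterion 1% intensity change per 10 min.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as hio
from .characterization import (
    focus_consistency,
    homogeneity,
    keystone,
    spectral_smile,
    temporal_stability,
)
from .cube import HyperCube, normalize
from .dispersion import DispersionModel
from .errors import HsicalError
from .illumination import DriftSpec, lamp_spectrum, led_panel_spectrum
from .scenes import SceneSpec
from .simulator import InstrumentConfig, simulate_scan
from .spatial import estimate_pixel_pitch, resolving_power, scan_aspect
from .spectral import calibrate_from_lamp_cubes, detect_peaks, measure_fwhm, mean_spectrum
from .verification import (
    TransmittanceSpectrum,
    erythema_index,
    fit_normalization_factor,
    normalized_absorbance,
    transmittance,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = ("spectral", "spatial", "characterize", "verify")

#: prerequisite stages that must be "done" before a stage may run
_PREREQUISITES = {
    "spectral": (),
    "spatial": (),
    "characterize": (),     # runs without spectral, but then reports px only
    "verify": ("spectral",),
}

DEFAULT_CONFIG: dict = {
    "schema_version": 1,
    "dispersion": {"a": 337.7, "b": 0.306, "c": 2.6e-5, "d": -5.4e-9},
    "detector": {"n_spectral": 2048, "pixel_pitch_um": 3.45},
    "slit_fwhm_nm": 2.9,
    "thresholds": {
        "contrast": 0.1,
        "line_tolerance_nm": 1.5,
        "clip_max": 1.5,
        "warmup_criterion": 0.01,
        "warmup_interval_min": 10.0,
        "focus_pass_nm": 1.0,
    },
    "aberrations": {
        "smile_px": 0.4,
        "keystone_px": 1.5,
        "vignetting_edge": 0.85,
        "drift": {"tau_min": 20.0, "intensity_drop": 0.10, "shift0_nm": 0.4},
    },
    "spectral_stage": {"n_slit": 16, "n_lines": 8, "laser_nm": 632.8},
    "spatial_stage": {
        # spatial targets are acquired with 16x spectral binning; geometry
        # does not depend on the spectral sampling
        "n_spectral": 128,
        "n_slit": 220,
        "object_pixel_mm": 0.12,
        "ronchi_lpmm": 0.5,
        "usaf_elements": [[0, 2], [0, 4], [0, 5], [0, 6], [1, 1]],
        "grid_period_mm": 4.32,
        "scan_speed_factor": 1.06,
        "spatial_fwhm_px": 3.4,
        "n_lines": 260,
    },
    "characterize_stage": {
        "n_slit": 600,
        "stability_times_min": [1, 2, 5, 10, 15, 20, 30, 45, 60],
        "smile_window": 50,
    },
    "verify_stage": {
        "inks": {
            "red": {"center_nm": 520.0, "width_nm": 40.0, "depth": 2.0,
                    "factor": 1.19},
            "blue": {"center_nm": 600.0, "width_nm": 45.0, "depth": 2.0,
                     "factor": 1.09},
        },
        "blank_T": 0.8,
        "green_band_nm": 540.0,
        "red_band_nm": 650.0,
    },
    "noise": {"gain": 2.0, "read_noise": 2.0},
    "stages": ["spectral", "spatial", "characterize", "verify"],
}


@dataclass
class ProtocolRun:
    """Stage statuses, config snapshot, seed registry and the merged report."""

    config: dict
    seed: int
    stage_status: dict[str, str] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    report: dict = field(default_factory=dict)
    output_paths: list[str] = field(default_factory=list)


def load_config(path: str | Path | None) -> dict:
    config = _deep_copy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _deep_update(config, user)
    _validate_config(config)
    return config


def _validate_config(config: dict) -> None:
    if config.get("schema_version") != 1:
        raise ValueError("unsupported or missing config schema_version (expected 1)")
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for stage in config["stages"]:
        if stage not in STAGE_ORDER:
            raise ValueError(f"unknown stage {stage!r}; expected {STAGE_ORDER}")


def _deep_copy(d):
    return json.loads(json.dumps(d))


def _deep_update(base: dict, patch: dict) -> None:
    for key, value in patch.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value


def run_protocol(
    config: dict | str | Path | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> ProtocolRun:
    """Execute the requested stages on simulator-generated cubes.

    Returns a :class:`ProtocolRun`; when ``out_dir`` is given the aggregated
    JSON report is written there as ``report.json``.  The report schema is
    stable: every stage key is present even when the stage was skipped.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    run = ProtocolRun(config=config, seed=seed)
    requested = [s for s in STAGE_ORDER if s in config["stages"]]
    for stage in STAGE_ORDER:
        run.stage_status[stage] = "pending" if stage in requested else "skipped"
        run.report[stage] = None

    context: dict = {}
    runners = {
        "spectral": _run_spectral,
        "spatial": _run_spatial,
        "characterize": _run_characterize,
        "verify": _run_verify,
    }
    for i, stage in enumerate(requested):
        missing = [
            p for p in _PREREQUISITES[stage]
            if run.stage_status.get(p) != "done"
        ]
        if missing:
            logger.error("[%s] prerequisite(s) %s not done; halting stage", stage, missing)
            run.stage_status[stage] = "failed"
            continue
        stage_seed = (seed * 1009 + 101 * i) % (2**31)
        run.seeds[stage] = stage_seed
        logger.info("[%s] running with seed %d", stage, stage_seed)
        try:
            run.report[stage] = runners[stage](config, stage_seed, context)
            run.stage_status[stage] = "done"
        except HsicalError as exc:
            logger.error("[%s] failed: %s", stage, exc)
            run.stage_status[stage] = "failed"
            run.report[stage] = {"error": str(exc)}
    run.report["stage_status"] = dict(run.stage_status)
    run.report["seed_registry"] = dict(run.seeds)
    run.report["config"] = config
    run.report["passed"] = _evaluate(run.report, config)
    run.report["timestamp"] = datetime.datetime.now().isoformat()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "report.json"
        path.write_text(json.dumps(run.report, indent=1, sort_keys=True, default=hio._json))
        run.output_paths.append(str(path))
    return run


# ---------------------------------------------------------------- stages


def _instrument(config: dict, **overrides) -> InstrumentConfig:
    ab = config["aberrations"]
    noise = config["noise"]
    base = dict(
        n_spectral=config["detector"]["n_spectral"],
        pixel_pitch_um=config["detector"]["pixel_pitch_um"],
        slit_fwhm_nm=config["slit_fwhm_nm"],
        smile_px=ab["smile_px"],
        keystone_px=ab["keystone_px"],
        gain=noise["gain"],
        read_noise=noise["read_noise"],
        drift=DriftSpec(enabled=True, **ab["drift"]),
    )
    base.update(overrides)
    n_slit = base.get("n_slit", 256)
    base["n_slit"] = n_slit
    if "vignetting" not in base:
        y = np.arange(n_slit)
        y_c = (n_slit - 1) / 2
        edge = ab["vignetting_edge"]
        base["vignetting"] = 1.0 - (1.0 - edge) * ((y - y_c) / y_c) ** 2
    return InstrumentConfig(**base)


def _model(config: dict) -> DispersionModel:
    d = config["dispersion"]
    return DispersionModel(
        d["a"], d["b"], d["c"], d["d"],
        n_spectral=config["detector"]["n_spectral"],
    )


def _run_spectral(config, seed, context):
    sc = config["spectral_stage"]
    model = _model(config)
    inst = _instrument(
        config, n_slit=sc["n_slit"], smile_px=0.0, keystone_px=0.0,
        vignetting=None,
    )
    scene = SceneSpec.uniform(1.0)
    cubes = {}
    for k, species in enumerate(("Hg/Ar", "H", "He", "Ne")):
        cube, _ = simulate_scan(
            scene, lamp_spectrum(species), model, inst,
            n_lines=sc["n_lines"], seed=seed + k,
        )
        cubes[species] = cube.values
    fit = calibrate_from_lamp_cubes(
        cubes,
        tolerance_nm=config["thresholds"]["line_tolerance_nm"],
        n_spectral=inst.n_spectral,
    )
    context["calibration"] = fit

    # monochromatic check: a laser-like single line through the instrument
    from .illumination import IlluminationSpec, LampLine

    laser = IlluminationSpec(lines=[LampLine(sc["laser_nm"], 100.0)])
    cube, _ = simulate_scan(scene, laser, model, inst, n_lines=20, seed=seed + 7)
    spec = mean_spectrum(cube.values)
    peaks = detect_peaks(spec, 0.2)
    laser_report = None
    if peaks:
        pk = max(peaks, key=lambda p: p.height)
        fwhm = measure_fwhm(spec, pk.centroid, fit.model)
        laser_report = {
            "recovered_nm": fit.model.wavelength_of_pixel(pk.centroid),
            "true_nm": sc["laser_nm"],
            "fwhm_nm": fwhm.fwhm_nm,
            "flags": fwhm.flags,
        }
    return {"fit": fit.to_dict(), "laser": laser_report}


def _scaled_model(config, n_spectral):
    """The instrument's dispersion under spectral binning to ``n_spectral``."""
    d = config["dispersion"]
    r = config["detector"]["n_spectral"] / n_spectral
    return DispersionModel(
        d["a"], d["b"] * r, d["c"] * r**2, d["d"] * r**3, n_spectral=n_spectral
    )


def _run_spatial(config, seed, context):
    sp = config["spatial_stage"]
    model = _scaled_model(config, sp["n_spectral"])
    common = dict(
        n_spectral=sp["n_spectral"],
        n_slit=sp["n_slit"],
        object_pixel_mm=sp["object_pixel_mm"],
        smile_px=0.0,
        keystone_px=0.0,
        vignetting=None,
        spatial_fwhm_slit_px=sp["spatial_fwhm_px"],
        spatial_fwhm_scan_px=sp["spatial_fwhm_px"] * 1.3,
    )
    led = led_panel_spectrum()

    inst = _instrument(config, **common)
    ronchi, _ = simulate_scan(
        SceneSpec.ronchi(sp["ronchi_lpmm"], axis="slit"), led, model, inst,
        n_lines=24, seed=seed,
    )
    pitch_slit = estimate_pixel_pitch(
        ronchi.values.mean(axis=2), sp["ronchi_lpmm"], "slit"
    )
    ronchi_scan, _ = simulate_scan(
        SceneSpec.ronchi(sp["ronchi_lpmm"], axis="scan"), led, model, inst,
        n_lines=sp["n_lines"], seed=seed + 1,
    )
    pitch_scan = estimate_pixel_pitch(
        ronchi_scan.values.mean(axis=2), sp["ronchi_lpmm"], "scan"
    )

    usaf_scene = SceneSpec.usaf1951([tuple(e) for e in sp["usaf_elements"]])
    usaf, truth = simulate_scan(
        usaf_scene, led, model, inst, n_lines=sp["n_lines"], seed=seed + 2
    )
    resolving = {}
    for axis in ("slit", "scan"):
        best, table = resolving_power(
            usaf, None, axis, truth["scene_geometry"],
            contrast_threshold=config["thresholds"]["contrast"],
        )
        resolving[axis] = {
            "best": None if best is None else
            {"group": best[0], "element": best[1], "freq_lpmm": best[2]},
            "contrast_table": [
                {"group": ec.group, "element": ec.element,
                 "freq_lpmm": ec.freq_lpmm, "contrasts": ec.contrasts}
                for ec in table
            ],
        }

    inst_fast = _instrument(
        config, **{**common, "scan_speed_factor": sp["scan_speed_factor"]}
    )
    grid, _ = simulate_scan(
        SceneSpec.square_grid(sp["grid_period_mm"]), led, model, inst_fast,
        n_lines=sp["n_lines"], seed=seed + 3,
    )
    elongation, correction = scan_aspect(grid)
    return {
        "pitch_mm_slit": pitch_slit,
        "pitch_mm_scan": pitch_scan,
        "pitch_mm_slit_2dp": round(pitch_slit, 2),
        "resolving": resolving,
        "elongation_percent": elongation,
        "speed_correction": correction,
    }


def _run_characterize(config, seed, context):
    ch = config["characterize_stage"]
    th = config["thresholds"]
    model = _model(config)
    fit = context.get("calibration")
    nm_model = fit.model if fit is not None else None
    led = led_panel_spectrum()
    scene = SceneSpec.uniform(1.0)

    inst = _instrument(config, n_slit=ch["n_slit"])
    white, _ = simulate_scan(scene, led, model, inst, n_lines=2, seed=seed)
    smile = spectral_smile(white, nm_model, window=ch["smile_window"])
    smile_report = {
        "max_abs_offset_px": smile.max_abs_offset_px,
        "max_abs_offset_nm": smile.max_abs_offset_nm,
        "units": "px+nm" if nm_model is not None else "px",
        "below_pixel_size": smile.below_pixel_size(),
    }

    grid_inst = _instrument(config, n_slit=ch["n_slit"], n_spectral=256)
    grid_model = _scaled_model(config, 256)
    grid, _ = simulate_scan(
        SceneSpec.square_grid(0.12 * ch["n_slit"] / 6.0), led, grid_model,
        grid_inst, n_lines=3, seed=seed + 1,
    )
    ks = keystone(grid.values[1], contrast_threshold=th["contrast"])
    keystone_report = {
        "max_abs_shift_px": ks.max_abs_shift_px,
        "central_half_max_px": ks.central_half_max_px,
        "n_skipped_bands": ks.n_skipped_bands,
    }

    hom = homogeneity(white, inst.vignetting_profile())
    hom_report = {
        "peak_offset_px": hom.peak_offset_px,
        "max_relative_deviation": hom.max_relative_deviation,
        "skew": hom.skew,
    }

    stab_inst = _instrument(config, n_slit=16)
    times = ch["stability_times_min"]
    series = [
        simulate_scan(scene, led, model, stab_inst, n_lines=2,
                      seed=seed + 10 + i, t_min=t)[0]
        for i, t in enumerate(times)
    ]
    stab = temporal_stability(
        series, times, nm_model,
        stability_criterion=th["warmup_criterion"],
        criterion_interval_min=th["warmup_interval_min"],
    )
    stab_report = {
        "warmup_time_min": stab.warmup_time_min,
        "max_abs_shift": float(np.nanmax(np.abs(stab.shifts))),
        "shift_units": stab.shift_units,
        "table": stab.table(),
    }

    focus_inst = _instrument(config, n_slit=16, spatial_fwhm_slit_px=0.0)
    defocus_inst = _instrument(config, n_slit=16, spatial_fwhm_slit_px=6.0)
    in_focus, _ = simulate_scan(scene, led, model, focus_inst, n_lines=4, seed=seed + 40)
    displaced, _ = simulate_scan(scene, led, model, defocus_inst, n_lines=4, seed=seed + 41)
    fr = focus_consistency(
        mean_spectrum(in_focus.values), mean_spectrum(displaced.values),
        nm_model, pass_threshold_nm=th["focus_pass_nm"],
    )
    focus_report = {
        "deltas": fr.deltas.tolist(),
        "units": fr.delta_units,
        "passed": fr.passed,
        "partial": fr.partial,
    }
    return {
        "smile": smile_report,
        "keystone": keystone_report,
        "homogeneity": hom_report,
        "stability": stab_report,
        "focus": focus_report,
    }


def _run_verify(config, seed, context):
    vf = config["verify_stage"]
    model = _model(config)
    fit = context["calibration"]
    axis = fit.model.wavelength_axis()
    inst = _instrument(
        config, n_slit=64, smile_px=0.0, keystone_px=0.0, vignetting=None
    )
    led = led_panel_spectrum()
    report_inks = {}
    for name, ink in vf["inks"].items():
        absorbance = _gaussian_absorber(ink)
        grid = np.arange(400.0, 1001.0, 1.0)
        reference = TransmittanceSpectrum(grid, np.exp(-absorbance(grid)))
        a_ref = normalized_absorbance(reference, 1.0)

        blank_spec = vf["blank_T"]
        sample_spec = lambda lam, ab=absorbance: (
            vf["blank_T"] * np.exp(-ab(np.asarray(lam, float))) / ink["factor"]
        )
        scene = SceneSpec.two_region(blank_spec, sample_spec, axis="slit")
        cube, _ = simulate_scan(scene, led, model, inst, n_lines=40, seed=seed)
        cube = HyperCube(cube.values, wavelength_nm=axis, meta=cube.meta)
        n_sl = cube.n_slit
        blank_region = (slice(8, 32), slice(2, n_sl // 2 - 4))
        sample_region = (slice(8, 32), slice(n_sl // 2 + 4, n_sl - 2))
        blank_vals = cube.values[:, blank_region[1], :]
        sample_vals = cube.values[:, sample_region[1], :]
        T = TransmittanceSpectrum(
            axis,
            sample_vals.mean(axis=(0, 1)) / blank_vals.mean(axis=(0, 1)),
        )
        agreement = fit_normalization_factor(T, a_ref)
        report_inks[name] = {
            "fitted_factor": agreement.factor,
            "true_factor": ink["factor"],
            "rmse": agreement.rmse,
            "peak_deltas_nm": agreement.peak_deltas_nm.tolist(),
        }

    erythema = _erythema_demo(config, model, axis, inst, seed)
    return {"inks": report_inks, "erythema": erythema}


def _gaussian_absorber(ink: dict):
    def absorbance(lam):
        lam = np.asarray(lam, dtype=float)
        return ink["depth"] * np.exp(
            -0.5 * ((lam - ink["center_nm"]) / ink["width_nm"]) ** 2
        )
    return absorbance


def _erythema_demo(config, model, axis, inst, seed):
    """A vessel phantom: a green-absorbing stripe on neutral background."""
    vf = config["verify_stage"]
    led = led_panel_spectrum()
    stripe = lambda lam: 0.6 - 0.35 * np.exp(
        -0.5 * ((np.asarray(lam, float) - vf["green_band_nm"]) / 35.0) ** 2
    )
    scene = SceneSpec.two_region(0.6, stripe, axis="slit")
    raw, _ = simulate_scan(scene, led, model, inst, n_lines=24, seed=seed + 5)
    white, _ = simulate_scan(SceneSpec.uniform(1.0), led, model, inst, n_lines=8,
                             seed=seed + 6)
    refl = normalize(raw, white, clip_max=config["thresholds"]["clip_max"])
    refl.wavelength_nm = axis
    emap = erythema_index(refl, vf["green_band_nm"], vf["red_band_nm"])
    half = emap.shape[1] // 2
    return {
        "stripe_mean_E": float(np.nanmean(emap[:, half + 4:])),
        "background_mean_E": float(np.nanmean(emap[:, : half - 4])),
    }


def _evaluate(report: dict, config: dict) -> dict:
    """Pass/fail summary against configured thresholds."""
    checks: dict[str, bool | None] = {
        "dispersion_residual_below_half_nm": None,
        "smile_below_pixel": None,
        "keystone_below_2px_central": None,
        "warmup_below_45min": None,
        "focus_consistent": None,
        "normalization_factor_recovered": None,
    }
    sp = report.get("spectral")
    if sp and "fit" in sp:
        checks["dispersion_residual_below_half_nm"] = (
            sp["fit"]["max_abs_residual_nm"] <= 0.5
        )
    ch = report.get("characterize")
    if ch and "smile" in ch:
        checks["smile_below_pixel"] = ch["smile"]["below_pixel_size"]
        checks["keystone_below_2px_central"] = (
            ch["keystone"]["central_half_max_px"] < 2.0
        )
        wu = ch["stability"]["warmup_time_min"]
        checks["warmup_below_45min"] = wu is not None and wu < 45.0
        checks["focus_consistent"] = ch["focus"]["passed"]
    vf = report.get("verify")
    if vf and "inks" in vf:
        checks["normalization_factor_recovered"] = all(
            abs(v["fitted_factor"] - v["true_factor"]) < 0.05
            for v in vf["inks"].values()
        )
    checks["all"] = all(v for v in checks.values() if v is not None)
    return checks


# ---------------------------------------------------------------- fixtures

FIXTURE_KINDS = (
    "lamps", "ronchi", "usaf", "square_grid", "white_stack", "drift_series",
    "ink_cells",
)


def make_fixtures(
    kind: str,
    seed: int,
    out_dir: str | Path,
    *,
    overwrite: bool = False,
    config: dict | None = None,
) -> list[Path]:
    """Write ENVI cubes + ground-truth JSON sidecars for tests and demos."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; expected {FIXTURE_KINDS}")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out_dir} is not empty; pass overwrite=True to replace"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or _deep_copy(DEFAULT_CONFIG)
    model = _model(config)
    led = led_panel_spectrum()
    written: list[Path] = []

    def _write(name: str, cube: HyperCube, truth: dict):
        path = out_dir / f"{name}.raw"
        hio.write_cube(cube, path)
        hio.write_ground_truth(truth, out_dir / f"{name}.json")
        written.extend([path, out_dir / f"{name}.json"])

    if kind == "lamps":
        inst = _instrument(config, n_slit=16, smile_px=0.0, vignetting=None)
        for k, species in enumerate(("Hg/Ar", "H", "He", "Ne")):
            cube, truth = simulate_scan(
                SceneSpec.uniform(1.0), lamp_spectrum(species), model, inst,
                n_lines=8, seed=seed + k,
            )
            _write(f"lamp_{species.replace('/', '')}", cube, truth)
    elif kind in ("ronchi", "usaf", "square_grid"):
        sp = config["spatial_stage"]
        inst = _instrument(
            config, n_slit=sp["n_slit"], n_spectral=sp["n_spectral"],
            object_pixel_mm=sp["object_pixel_mm"],
            spatial_fwhm_slit_px=sp["spatial_fwhm_px"],
        )
        smodel = _scaled_model(config, sp["n_spectral"])
        scene = {
            "ronchi": SceneSpec.ronchi(sp["ronchi_lpmm"], axis="slit"),
            "usaf": SceneSpec.usaf1951([tuple(e) for e in sp["usaf_elements"]]),
            "square_grid": SceneSpec.square_grid(sp["grid_period_mm"]),
        }[kind]
        cube, truth = simulate_scan(scene, led, smodel, inst,
                                    n_lines=sp["n_lines"], seed=seed)
        _write(kind, cube, truth)
    elif kind == "white_stack":
        inst = _instrument(config, n_slit=128)
        for i in range(3):
            cube, truth = simulate_scan(
                SceneSpec.uniform(1.0), led, model, inst, n_lines=4,
                seed=seed + i,
            )
            _write(f"white_{i}", cube, truth)
    elif kind == "drift_series":
        inst = _instrument(config, n_slit=16)
        for i, t in enumerate(config["characterize_stage"]["stability_times_min"]):
            cube, truth = simulate_scan(
                SceneSpec.uniform(1.0), led, model, inst, n_lines=2,
                seed=seed + i, t_min=float(t),
            )
            _write(f"white_t{t:04.0f}min", cube, truth)
    elif kind == "ink_cells":
        inst = _instrument(config, n_slit=64, smile_px=0.0, vignetting=None)
        for name, ink in config["verify_stage"]["inks"].items():
            absorbance = _gaussian_absorber(ink)
            grid = np.arange(400.0, 1001.0, 1.0)
            sample = (grid, config["verify_stage"]["blank_T"]
                      * np.exp(-absorbance(grid)) / ink["factor"])
            scene = SceneSpec.two_region(
                config["verify_stage"]["blank_T"], sample, axis="slit"
            )
            cube, truth = simulate_scan(scene, led, model, inst, n_lines=40,
                                        seed=seed)
            _write(f"ink_{name}", cube, truth)
    return written
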
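"""End-to-end orchestration: quantification → profiling → statistics →
segmentation → scoring, with figure analogues and a parameter-complete log.

Two input modes share the same stages:

* **scenario mode** (default): a seeded :class:`~senoscope.synthetic.ScenarioSpec`
  generates every input in memory — cell-field images are quantified through
  the real image pipeline, lysosomal event populations feed the histogram
  arm, mitochondrial per-cell densities feed the CDF arm, and field counts /
  flow events feed the scoring arm;
* **manifest mode**: a manifest CSV (image_path, mask_path, donor, inducer,
  cell_id) points at real images and masks, with optional ``counts.csv`` and
  ``flow_events.csv`` next to it.

All tabular outputs are CSV (figures are views of those tables, never sole
outputs); re-running an identical config reproduces identical bytes.  Axis
limits are computed once over the pooled run and frozen so every condition's
panel is directly comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import mito, peakstats, profiling, scoring, synthetic
from .errors import (ConfigError, DegenerateInputError, EstimabilityError,
                     SampleSizeError)
from .quantify import quantify_manifest, records_to_frame

__all__ = ["RunConfig", "RunReport", "run_pipeline", "render_figures"]


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are echoed into the run log."""

    out_dir: str = "senoscope_run"
    manifest: str | None = None  # None -> synthetic scenario mode
    seed: int = 0
    scenario: dict = field(default_factory=dict)  # ScenarioSpec overrides
    # binning / peak detection (lysosomal arm)
    n_bins: int = 30_000
    prominence: float | None = None  # counts/cell; None -> 2% of curve max
    min_distance: int | None = None  # bins; None -> 1% of n_bins
    smooth_window: int | None = None  # bins; None -> 2% of n_bins
    # CDF segmentation (mitochondrial arm)
    grid_size: int = 1000
    cdf_smooth_window: int | None = None  # grid points; None -> 2% of grid
    # statistics
    donor_ref: str = "YD"
    inducer_ref: str = "C10"
    fdr_level: float = 0.05
    min_peaks: int = 2
    redistribution_threshold_pp: float = 5.0
    # stage toggles
    run_quantification: bool = True
    run_profiling: bool = True
    run_statistics: bool = True
    run_segmentation: bool = True
    run_scoring: bool = True
    make_figures: bool = True
    write_profiles: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ConfigError(f"fdr_level must lie in (0,1), got {self.fdr_level}")
        for name in ("n_bins", "grid_size", "min_peaks"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.redistribution_threshold_pp < 0:
            raise ConfigError("redistribution_threshold_pp must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        return cls(**json.loads(path.read_text()))


@dataclass
class RunReport:
    """Handles to every table the run produced, plus output paths."""

    out_dir: Path
    quantification: pd.DataFrame | None = None
    peaks: pd.DataFrame | None = None
    coefficients: pd.DataFrame | None = None
    shape_tests: pd.DataFrame | None = None
    diagnostics: dict | None = None
    mito_segments: pd.DataFrame | None = None
    redistribution: pd.DataFrame | None = None
    scores: pd.DataFrame | None = None
    flow: pd.DataFrame | None = None
    log_lines: list = field(default_factory=list)


def _effective_smooth(window: int | None, default_frac: float, n: int) -> int | None:
    if window is not None:
        return window if window > 1 else None
    return max(1, round(default_frac * n))


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all enabled stages and write CSV/JSON/figure outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out_dir=out)
    log = report.log_lines
    log.append("senoscope run")
    for key, value in asdict(config).items():
        log.append(f"config {key} = {value!r}")

    manifest_mode = config.manifest is not None
    if manifest_mode:
        manifest_path = Path(config.manifest)
        if not manifest_path.exists():
            raise ConfigError(f"manifest not found: {manifest_path}")
        spec = None
    else:
        spec = synthetic.ScenarioSpec(seed=config.seed, **config.scenario)
        log.append(f"scenario conditions = {len(spec.conditions)}")

    # ---- stage 1: quantification -------------------------------------
    densities_by_curve: dict[str, list[np.ndarray]] = {}
    mito_by_condition: dict[str, np.ndarray] = {}
    counts_table: pd.DataFrame | None = None
    flow_tables: list[pd.DataFrame] = []

    if manifest_mode:
        records = quantify_manifest(manifest_path)
        report.quantification = records_to_frame(records)
        for rec in records:
            curve = f"{rec.donor}:{rec.inducer}"
            densities_by_curve.setdefault(curve, []).append(rec.density_values)
        for curve in densities_by_curve:
            mito_by_condition[curve] = np.array(
                [rec.mean_density for rec in records
                 if f"{rec.donor}:{rec.inducer}" == curve])
        counts_path = manifest_path.parent / "counts.csv"
        if counts_path.exists():
            counts_table = pd.read_csv(counts_path).fillna({"control": ""})
        flow_path = manifest_path.parent / "flow_events.csv"
        if flow_path.exists():
            events = pd.read_csv(flow_path)
            flow_tables = [g.reset_index(drop=True)
                           for _, g in events.groupby("condition", sort=True)]
    else:
        from .image_io import CellMask, image_from_array
        from .quantify import quantify_cell

        quant_records = []
        counts_frames = []
        for donor, inducer in spec.conditions:
            curve = f"{donor}:{inducer}"
            if config.run_quantification:
                field_fix = synthetic.generate_cell_field(
                    spec, donor, inducer, image_size=(256, 256), n_cells=5)
                image = image_from_array(field_fix.image,
                                         pixel_size_x=field_fix.pixel_size_um,
                                         pixel_size_y=field_fix.pixel_size_um,
                                         source=curve)
                for k, mask in enumerate(field_fix.masks):
                    quant_records.append(quantify_cell(
                        image, CellMask(mask), cell_id=f"{curve}:c{k}",
                        donor=donor, inducer=inducer))
            cells, _truth = synthetic.generate_intensity_population(
                spec, donor, inducer)
            densities_by_curve[curve] = cells
            values, _ = synthetic.generate_mito_population(spec, donor, inducer)
            mito_by_condition[curve] = values
            counts, events, _ = synthetic.generate_count_tables(
                spec, donor, inducer)
            counts_frames.append(counts)
            flow_tables.append(pd.DataFrame({"condition": curve,
                                             "intensity": events}))
        if quant_records:
            report.quantification = records_to_frame(quant_records)
        counts_table = pd.concat(counts_frames, ignore_index=True)

    if report.quantification is not None:
        _write(report.quantification, out / "cells.csv")
        log.append(f"quantification: {len(report.quantification)} cells")

    # ---- stage 2: histogram profiling + peak detection ---------------
    profiles: dict[str, profiling.HistogramProfile] = {}
    peaksets: dict[str, profiling.PeakSet] = {}
    if config.run_profiling:
        smooth = _effective_smooth(config.smooth_window, 0.02, config.n_bins)
        peak_frames = []
        for curve in sorted(densities_by_curve):
            cells = densities_by_curve[curve]
            try:
                profile = profiling.build_profile(cells, n_bins=config.n_bins,
                                                  curve_id=curve)
            except DegenerateInputError as exc:
                log.append(f"profiling skipped for {curve}: {exc}")
                continue
            profiles[curve] = profile
            log.append(f"profile {curve}: n_cells={profile.n_cells} "
                       f"zero_excluded={profile.n_zero_excluded}")
            peakset = profiling.detect_peaks(
                profile, prominence=config.prominence,
                min_distance=config.min_distance, smooth_window=smooth)
            peaksets[curve] = peakset
            peak_frames.append(peakset.to_frame())
            if config.write_profiles:
                _write(profile.to_frame(),
                       out / f"profile_{curve.replace(':', '_')}.csv")
        if peak_frames:
            report.peaks = pd.concat(peak_frames, ignore_index=True)
            _write(report.peaks, out / "peaks.csv")
            log.append(f"peaks: {len(report.peaks)} local maxima across "
                       f"{len(peaksets)} curves")

    # ---- stage 3: peak statistics ------------------------------------
    if config.run_statistics and report.peaks is not None \
            and len(report.peaks) > 0:
        obs = report.peaks.copy()
        obs[["donor", "inducer"]] = obs["curve_id"].str.split(":", expand=True)
        obs = obs.rename(columns={"log10_position": "log10_xpeak"})
        diagnostics: dict = {"note": peakstats.PSEUDOREPLICATION_NOTE}
        try:
            lmm = peakstats.fit_peak_lmm(obs, donor_ref=config.donor_ref,
                                         inducer_ref=config.inducer_ref)
            report.coefficients = lmm.fixed_effects
            _write(lmm.fixed_effects, out / "lmm_coefficients.csv")
            diagnostics["random_intercept_variance"] = \
                lmm.random_intercept_variance
            if lmm.residuals.size >= 3:
                w, p_w = peakstats.residual_normality(lmm)
                diagnostics["shapiro_W"] = w
                diagnostics["shapiro_p"] = p_w
        except (SampleSizeError, EstimabilityError, ValueError) as exc:
            log.append(f"LMM skipped: {exc}")
        donor_groups = {d: g["log10_xpeak"].to_numpy()
                        for d, g in obs.groupby("donor")
                        if len(g) >= 2}
        if len(donor_groups) >= 2:
            f_lev, p_lev = peakstats.variance_homogeneity(donor_groups)
            diagnostics["levene_F"] = f_lev
            diagnostics["levene_p"] = p_lev
        by_inducer = {
            inducer: {donor: g2["log10_xpeak"].to_numpy()
                      for donor, g2 in g.groupby("donor")}
            for inducer, g in obs.groupby("inducer")}
        shape_results = peakstats.shape_compare(by_inducer,
                                                min_peaks=config.min_peaks)
        report.shape_tests = peakstats.shape_results_to_frame(shape_results)
        _write(report.shape_tests, out / "shape_tests.csv")
        for r in shape_results:
            if not r.included:
                log.append(f"shape test excluded {r.inducer}: "
                           f"{r.exclusion_reason}")
        report.diagnostics = diagnostics
        (out / "diagnostics.json").write_text(
            json.dumps(diagnostics, indent=2, sort_keys=True))

    # ---- stage 4: mitochondrial CDF segmentation ---------------------
    if config.run_segmentation and mito_by_condition:
        cdf_profiles = []
        for curve in sorted(mito_by_condition):
            values = mito_by_condition[curve]
            try:
                cdf = mito.build_cdf(values, grid_size=config.grid_size,
                                     condition=curve)
            except DegenerateInputError as exc:
                log.append(f"segmentation skipped for {curve}: {exc}")
                continue
            smooth = _effective_smooth(config.cdf_smooth_window, 0.02,
                                       len(cdf.u_grid))
            cdf = mito.segment_profile(cdf, smooth_window=smooth)
            if cdf.single_population:
                log.append(f"segmentation {curve}: single-population flag")
            cdf_profiles.append(cdf)
        if cdf_profiles:
            report.mito_segments = mito.profiles_to_frame(cdf_profiles)
            _write(report.mito_segments, out / "mito_segments.csv")
            redist_rows = []
            by_cond = {p.condition: p for p in cdf_profiles}
            for curve, profile in by_cond.items():
                donor = curve.split(":")[0]
                ref_curve = f"{donor}:{config.inducer_ref}"
                ref = by_cond.get(ref_curve)
                if ref is None or curve == ref_curve:
                    continue
                if (ref.fractions is None or len(ref.fractions) != 3
                        or profile.fractions is None
                        or len(profile.fractions) != 3):
                    continue
                summary = mito.redistribution(
                    ref.fractions, profile.fractions,
                    threshold=config.redistribution_threshold_pp,
                    condition_pair=(ref_curve, curve))
                redist_rows.append({
                    "reference": ref_curve, "treatment": curve,
                    "delta_dpsi1": summary.deltas[0],
                    "delta_dpsi2": summary.deltas[1],
                    "delta_dpsi3": summary.deltas[2],
                    "sig_dpsi1": summary.significant[0],
                    "sig_dpsi2": summary.significant[1],
                    "sig_dpsi3": summary.significant[2],
                })
            if redist_rows:
                report.redistribution = pd.DataFrame(redist_rows)
                _write(report.redistribution, out / "redistribution.csv")
            report._cdf_profiles = cdf_profiles  # for figure rendering

    # ---- stage 5: SA-β-Gal scoring + flow summaries ------------------
    if config.run_scoring and counts_table is not None and len(counts_table):
        report.scores = scoring.score_conditions(counts_table)
        _write(report.scores, out / "scores.csv")
        undefined = report.scores[~report.scores["SI_defined"]]
        for cond in undefined["condition"]:
            log.append(f"SI undefined for {cond}")
    if config.run_scoring and flow_tables:
        flow_rows = []
        for table in flow_tables:
            cond = str(table["condition"].iloc[0])
            summary = scoring.flow_summary(table["intensity"].to_numpy(),
                                           condition=cond)
            flow_rows.append({"condition": cond, "MFI": summary.mfi,
                              "IQR": summary.iqr,
                              "n_events": summary.n_events})
        report.flow = pd.DataFrame(flow_rows)
        _write(report.flow, out / "flow_summary.csv")

    # ---- figures ------------------------------------------------------
    if config.make_figures:
        render_figures(report, profiles=profiles, peaksets=peaksets)

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return report


def render_figures(report: RunReport,
                   profiles: dict | None = None,
                   peaksets: dict | None = None) -> list[Path]:
    """Render figure analogues from a run's outputs.

    Log-log histogram panels per donor (shared axis limits across every
    condition), CDF panels with θ crosses, stacked Δψ fraction bars and peak
    box-summaries by donor and by inducer.  Missing sections are skipped.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = report.out_dir
    written: list[Path] = []

    if profiles:
        donors = sorted({c.split(":")[0] for c in profiles})
        positives = [p.mean_counts[p.mean_counts > 0] for p in profiles.values()]
        ymax = max(p.mean_counts.max() for p in profiles.values())
        ymin = min(p.min() for p in positives if p.size) if positives else 1e-3
        xlo = min(p.bin_edges[0] for p in profiles.values())
        xhi = max(p.bin_edges[-1] for p in profiles.values())
        fig, axes = plt.subplots(1, max(len(donors), 1),
                                 figsize=(4 * max(len(donors), 1), 3.2),
                                 squeeze=False)
        for ax, donor in zip(axes[0], donors):
            for curve, profile in sorted(profiles.items()):
                if not curve.startswith(donor + ":"):
                    continue
                centres = np.sqrt(profile.bin_edges[:-1] * profile.bin_edges[1:])
                ax.plot(centres, profile.mean_counts, lw=0.6,
                        label=curve.split(":")[1])
            ax.set_xscale("log")
            ax.set_yscale("log")
            ax.set_xlim(xlo, xhi)
            ax.set_ylim(max(ymin, 1e-6), ymax * 1.5)
            ax.set_title(donor)
            ax.set_xlabel("intensity density (a.u./µm²)")
            ax.legend(fontsize=5)
        axes[0][0].set_ylabel("counts per bin per cell")
        fig.tight_layout()
        path = out / "fig_profiles.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    cdf_profiles = getattr(report, "_cdf_profiles", None)
    if cdf_profiles:
        fig, ax = plt.subplots(figsize=(5, 3.4))
        for profile in cdf_profiles:
            ax.plot(profile.u_grid, profile.alpha, lw=0.8,
                    label=profile.condition)
            for theta in (profile.thetas or ()):
                ax.plot(theta, profile.alpha_at(theta), "x", color="k",
                        ms=6, mew=1.5)
        ax.set_xlabel("u = log10(X) (a.u./µm²)")
        ax.set_ylabel("α(u), % of cells")
        ax.legend(fontsize=5)
        fig.tight_layout()
        path = out / "fig_cdf.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if report.mito_segments is not None and len(report.mito_segments):
        seg = report.mito_segments.dropna(subset=["dpsi1"])
        fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(seg)), 3.4))
        bottom = np.zeros(len(seg))
        for col, label in (("dpsi1", "Δψ1 depolarised"),
                           ("dpsi2", "Δψ2 mid"),
                           ("dpsi3", "Δψ3 hyperpolarised")):
            heights = seg[col].fillna(0).to_numpy()
            ax.bar(seg["condition"], heights, bottom=bottom, label=label)
            bottom += heights
        ax.set_ylabel("% of cells")
        ax.legend(fontsize=6)
        ax.tick_params(axis="x", rotation=90, labelsize=5)
        fig.tight_layout()
        path = out / "fig_fractions.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if report.peaks is not None and len(report.peaks):
        peaks = report.peaks.copy()
        peaks[["donor", "inducer"]] = peaks["curve_id"].str.split(":",
                                                                  expand=True)
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
        for ax, by in zip(axes, ("donor", "inducer")):
            groups = [g["log10_position"].to_numpy()
                      for _, g in peaks.groupby(by)]
            labels = [name for name, _ in peaks.groupby(by)]
            ax.boxplot(groups, tick_labels=labels)
            ax.set_ylabel("log10(X_peak)")
            ax.set_title(f"peak positions by {by}")
        fig.tight_layout()
        path = out / "fig_peak_boxes.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    return written
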
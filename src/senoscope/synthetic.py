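"""Synthetic study generator with known ground truth.

The study's raw microscopy and count data are not deposited, so every input
the pipeline consumes is emulated here with the structure the analyses
assume, and with the generating truth recorded so recovery can be tested:

* lysosomal per-cell intensity-density populations drawn from mixtures of
  1-3 lognormal components whose log10 positions shift additively by donor
  (YD 0, OD +0.3, RS +0.5), by inducer (relative to the C10 control) and by
  a per-curve random intercept — the structure the mixed model estimates;
* direct peak-position observations with a known per-peak slope for
  mixed-model calibration;
* masked cell-field images whose elliptical cells have exact pixel areas and
  whose in-mask pixel values encode mixture draws (so per-pixel densities
  reproduce the mixture exactly);
* bimodal mitochondrial per-cell mean densities with analytically known
  segment fractions;
* SA-β-Gal field counts binomial around a known S% with treated totals
  around a known V%rel, and lognormal flow-cytometry events around a known
  MFI.

A single scenario seed fans out deterministically to per-stream child seeds
(keyed by stream name and condition), so identical spec + seed reproduces
every table byte-for-byte and modules can be regenerated independently.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CapacityError, ScenarioError

__all__ = [
    "Component",
    "ScenarioSpec",
    "IntensityTruth",
    "CellField",
    "generate_intensity_population",
    "generate_peak_observations",
    "generate_cell_field",
    "generate_mito_population",
    "generate_count_tables",
    "analytic_fractions",
    "synthesize_to_dir",
]


@dataclass(frozen=True)
class Component:
    """One lognormal mixture component on the log10 intensity axis."""

    log_mode: float  # log10 a.u./µm²
    log_sd: float  # log10 units
    weight: float


def _default_lyso_components() -> tuple[Component, ...]:
    return (Component(1.0, 0.15, 0.5), Component(2.5, 0.15, 0.5))


def _default_mito_components() -> tuple[Component, ...]:
    return (Component(1.0, 0.25, 0.3), Component(3.0, 0.25, 0.7))


@dataclass
class ScenarioSpec:
    """Full parameterisation of a synthetic study.

    Donor and inducer offsets are additive log10 shifts of every mixture
    component (inducers relative to the C10 control).  SA-β-Gal truth is a
    per-donor baseline S% plus a per-inducer boost, clipped to [0, 100];
    V%rel truth is per inducer.  Flow MFIs are fold changes over the C10
    baseline.
    """

    donors: dict = field(default_factory=lambda: {"YD": 0.0, "OD": 0.3, "RS": 0.5})
    inducers: dict = field(default_factory=lambda: {
        "C10": 0.0, "C1": 0.15, "Doxo": 0.35, "Cis": 0.30,
        "Eto": 0.25, "Bleo": 0.40})
    lyso_components: tuple = field(default_factory=_default_lyso_components)
    mito_components: tuple = field(default_factory=_default_mito_components)
    curve_intercept_sd: float = 0.1
    n_cells_per_condition: int = 200
    events_per_cell: int = 500
    # SA-β-Gal truth: donor baselines and inducer boosts (percentage points)
    s_percent_baseline: dict = field(default_factory=lambda: {
        "YD": 2.5, "OD": 9.1, "RS": 16.3})
    s_percent_boost: dict = field(default_factory=lambda: {
        "C10": 0.0, "C1": 10.0, "Doxo": 55.0, "Cis": 70.0,
        "Eto": 50.0, "Bleo": 65.0})
    v_rel_percent: dict = field(default_factory=lambda: {
        "C10": 100.0, "C1": 95.0, "Doxo": 88.0, "Cis": 62.0,
        "Eto": 86.0, "Bleo": 58.0})
    flow_mfi_fold: dict = field(default_factory=lambda: {
        "C10": 1.0, "C1": 1.75, "Doxo": 2.5, "Cis": 3.5,
        "Eto": 2.5, "Bleo": 3.5})
    flow_mfi_baseline: float = 100.0
    flow_log_sd: float = 0.2
    n_fields: int = 5
    cells_per_field: int = 200
    flow_events: int = 1000
    pixel_size_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.lyso_components = tuple(
            c if isinstance(c, Component) else Component(*c)
            for c in self.lyso_components)
        self.mito_components = tuple(
            c if isinstance(c, Component) else Component(*c)
            for c in self.mito_components)
        self.validate()

    def validate(self) -> None:
        for name, comps in (("lyso", self.lyso_components),
                            ("mito", self.mito_components)):
            if not 1 <= len(comps) <= 3:
                raise ScenarioError(
                    f"{name} mixture needs 1-3 components, got {len(comps)}")
            weights = sum(c.weight for c in comps)
            if abs(weights - 1.0) > 1e-9:
                raise ScenarioError(
                    f"{name} mixture weights sum to {weights}, expected 1")
            if any(c.log_sd < 0 or c.weight <= 0 for c in comps):
                raise ScenarioError(f"invalid {name} component parameters")
        if not 95 <= self.n_cells_per_condition <= 600:
            raise ScenarioError(
                "n_cells_per_condition must lie in [95, 600], got "
                f"{self.n_cells_per_condition}")
        for count in (self.events_per_cell, self.n_fields,
                      self.cells_per_field, self.flow_events):
            if count <= 0:
                raise ScenarioError("all counts must be positive")
        if self.curve_intercept_sd < 0 or self.flow_log_sd < 0 \
                or self.pixel_size_um <= 0:
            raise ScenarioError("scale parameters must be non-negative")

    @property
    def conditions(self) -> list[tuple[str, str]]:
        return [(d, i) for d in self.donors for i in self.inducers]

    def true_s_percent(self, donor: str, inducer: str) -> float:
        return float(np.clip(self.s_percent_baseline[donor]
                             + self.s_percent_boost[inducer], 0.0, 100.0))

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["lyso_components"] = [list(astuple) for astuple in
                                      ((c.log_mode, c.log_sd, c.weight)
                                       for c in self.lyso_components)]
        payload["mito_components"] = [[c.log_mode, c.log_sd, c.weight]
                                      for c in self.mito_components]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioSpec":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def _rng(seed: int, *keys: str) -> np.random.Generator:
    """Deterministic child generator for a named stream."""
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class IntensityTruth:
    """Generating truth for one curve (one donor-inducer condition)."""

    curve_id: str
    modes: tuple[float, ...]  # ascending log10 positions incl. all shifts
    curve_intercept: float
    shift: float  # donor + inducer offset


def _sample_mixture(rng: np.random.Generator, components: Sequence[Component],
                    shift: float, n: int) -> np.ndarray:
    weights = np.array([c.weight for c in components])
    choice = rng.choice(len(components), size=n, p=weights / weights.sum())
    log_values = np.empty(n)
    for k, comp in enumerate(components):
        sel = choice == k
        log_values[sel] = rng.normal(comp.log_mode + shift, comp.log_sd,
                                     size=int(sel.sum()))
    return 10.0 ** log_values


def generate_intensity_population(spec: ScenarioSpec, donor: str, inducer: str
                                  ) -> tuple[list[np.ndarray], IntensityTruth]:
    """Per-cell lysosomal event collections for one condition.

    Every cell of the condition shares the curve's random intercept (the
    curve, not the cell, is the grouping unit); events are lognormal mixture
    draws shifted by donor + inducer + intercept.
    """
    if donor not in spec.donors or inducer not in spec.inducers:
        raise ScenarioError(f"unknown condition ({donor}, {inducer})")
    rng = _rng(spec.seed, "lyso", donor, inducer)
    shift = spec.donors[donor] + spec.inducers[inducer]
    intercept = rng.normal(0.0, spec.curve_intercept_sd) \
        if spec.curve_intercept_sd > 0 else 0.0
    total_shift = shift + intercept
    cells = [_sample_mixture(rng, spec.lyso_components, total_shift,
                             spec.events_per_cell)
             for _ in range(spec.n_cells_per_condition)]
    modes = tuple(sorted(c.log_mode + total_shift for c in spec.lyso_components))
    truth = IntensityTruth(curve_id=f"{donor}:{inducer}", modes=modes,
                           curve_intercept=intercept, shift=shift)
    return cells, truth


def generate_peak_observations(spec: ScenarioSpec,
                               n_curves: int = 60,
                               base_intercept: float = 1.0,
                               peak_slope: float = 0.4,
                               residual_sd: float = 0.05,
                               seed: int | None = None,
                               ) -> tuple[pd.DataFrame, dict]:
    """Direct peak-position observations with known fixed effects.

    Curves cycle through every donor-inducer combination; each contributes
    1-3 peaks with positions
    ``base + donor + inducer + slope*peak_id + b_curve + eps``.
    Returns the observation table and the generating truth (per-term fixed
    effects keyed like the fitted coefficient table, plus variances).
    """
    rng = _rng(spec.seed if seed is None else seed, "lmm")
    combos = spec.conditions
    rows = []
    for c in range(n_curves):
        donor, inducer = combos[c % len(combos)]
        b_curve = rng.normal(0.0, spec.curve_intercept_sd)
        n_peaks = int(rng.integers(1, 4))
        for peak_id in range(1, n_peaks + 1):
            value = (base_intercept + spec.donors[donor]
                     + spec.inducers[inducer] + peak_slope * peak_id
                     + b_curve + rng.normal(0.0, residual_sd))
            rows.append((value, donor, inducer, peak_id, f"curve{c:03d}"))
    table = pd.DataFrame(rows, columns=["log10_xpeak", "donor", "inducer",
                                        "peak_id", "curve_id"])
    truth = {f"donor[{d}]": off for d, off in spec.donors.items() if d != "YD"}
    truth.update({f"inducer[{i}]": off for i, off in spec.inducers.items()
                  if i != "C10"})
    truth["peak_id"] = peak_slope
    truth["Intercept"] = base_intercept
    truth["curve_intercept_variance"] = spec.curve_intercept_sd ** 2
    truth["residual_variance"] = residual_sd ** 2
    return table, truth


@dataclass
class CellField:
    """One synthetic field: image plane, per-cell masks and generating truth."""

    image: np.ndarray
    masks: list  # boolean arrays, one per cell
    pixel_size_um: float
    cell_values: list  # per-cell mixture draws (intensity densities)
    cell_areas_um2: list


def _ellipse_mask(shape: tuple[int, int], centre: tuple[float, float],
                  semi_axes: tuple[float, float]) -> np.ndarray:
    rows, cols = np.ogrid[:shape[0], :shape[1]]
    r0, c0 = centre
    a, b = semi_axes
    return ((rows - r0) / a) ** 2 + ((cols - c0) / b) ** 2 <= 1.0


def generate_cell_field(spec: ScenarioSpec, donor: str, inducer: str,
                        image_size: tuple[int, int] = (512, 512),
                        n_cells: int = 10,
                        semi_axis_range: tuple[float, float] = (8.0, 14.0),
                        max_attempts: int = 2000) -> CellField:
    """Paint non-overlapping elliptical cells on a zero background.

    Each cell's in-mask pixel values are ``density_draw x cell_area`` so the
    quantification stage (raw / area) recovers the condition's mixture draws
    exactly; masks are exact by construction.
    """
    if n_cells <= 0:
        raise ScenarioError("n_cells must be positive")
    rng = _rng(spec.seed, "field", donor, inducer)
    shift = spec.donors[donor] + spec.inducers[inducer]
    image = np.zeros(image_size, dtype=float)
    occupied = np.zeros(image_size, dtype=bool)
    masks, cell_values, areas = [], [], []
    attempts = 0
    while len(masks) < n_cells:
        if attempts >= max_attempts:
            raise CapacityError(
                f"placed {len(masks)}/{n_cells} cells in {max_attempts} "
                "attempts; lower the density or enlarge the field")
        attempts += 1
        a, b = rng.uniform(*semi_axis_range, size=2)
        r0 = rng.uniform(a + 1, image_size[0] - a - 1)
        c0 = rng.uniform(b + 1, image_size[1] - b - 1)
        mask = _ellipse_mask(image_size, (r0, c0), (a, b))
        if (mask & occupied).any():
            continue
        area_um2 = mask.sum() * spec.pixel_size_um ** 2
        draws = _sample_mixture(rng, spec.lyso_components, shift,
                                int(mask.sum()))
        image[mask] = draws * area_um2
        occupied |= mask
        masks.append(mask)
        cell_values.append(draws)
        areas.append(float(area_um2))
    return CellField(image=image, masks=masks,
                     pixel_size_um=spec.pixel_size_um,
                     cell_values=cell_values, cell_areas_um2=areas)


def generate_mito_population(spec: ScenarioSpec, donor: str, inducer: str
                             ) -> tuple[np.ndarray, dict]:
    """Per-cell mitochondrial mean densities from a bimodal mixture.

    Returns the values and a truth dict with the shifted components, the
    analytic density modes, and a callable-free analytic fraction helper via
    :func:`analytic_fractions`.
    """
    if len(spec.mito_components) < 2:
        raise ScenarioError("mitochondrial scenario needs 2 components")
    rng = _rng(spec.seed, "mito", donor, inducer)
    shift = spec.donors[donor] + spec.inducers[inducer]
    values = _sample_mixture(rng, spec.mito_components, shift,
                             spec.n_cells_per_condition)
    shifted = tuple(Component(c.log_mode + shift, c.log_sd, c.weight)
                    for c in spec.mito_components)
    truth = {
        "components": shifted,
        "modes": tuple(sorted(c.log_mode for c in shifted)),
        "weights": tuple(c.weight for c in spec.mito_components),
    }
    return values, truth


def analytic_fractions(components: Sequence[Component], theta1: float,
                       theta2: float) -> tuple[float, float, float]:
    """Exact mixture probabilities of the three u-segments at (θ1, θ2)."""
    def mixture_cdf(u: float) -> float:
        return float(sum(c.weight * stats.norm.cdf(u, loc=c.log_mode,
                                                   scale=c.log_sd)
                         for c in components))

    a1 = 100.0 * mixture_cdf(theta1)
    a2 = 100.0 * mixture_cdf(theta2)
    return (a1, a2 - a1, 100.0 - a1 - (a2 - a1))


def generate_count_tables(spec: ScenarioSpec, donor: str, inducer: str
                          ) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """SA-β-Gal field counts and flow events for one condition.

    Control (C10) totals are Poisson around ``cells_per_field``; treated
    totals around ``cells_per_field x V%rel/100``; positives are binomial
    at the condition's true S%.  Flow events are lognormal around the
    condition MFI.
    """
    rng = _rng(spec.seed, "counts", donor, inducer)
    true_s = spec.true_s_percent(donor, inducer)
    true_v = float(spec.v_rel_percent[inducer])
    expected_total = spec.cells_per_field * true_v / 100.0
    rows = []
    for f in range(spec.n_fields):
        n_total = int(rng.poisson(expected_total))
        n_pos = int(rng.binomial(n_total, true_s / 100.0)) if n_total else 0
        rows.append({
            "condition": f"{donor}:{inducer}",
            "field_id": f"{donor}:{inducer}:f{f}",
            "n_positive": n_pos,
            "n_total": n_total,
            "control": f"{donor}:C10" if inducer != "C10" else "",
        })
    counts = pd.DataFrame(rows)
    mfi = spec.flow_mfi_baseline * spec.flow_mfi_fold[inducer]
    events = mfi * 10.0 ** rng.normal(0.0, spec.flow_log_sd, spec.flow_events)
    truth = {"s_percent": true_s, "v_rel_percent": true_v, "mfi": mfi}
    return counts, events, truth


def synthesize_to_dir(spec: ScenarioSpec, out_dir: str | Path,
                      image_size: tuple[int, int] = (256, 256),
                      cells_per_image: int = 5) -> Path:
    """Write a complete on-disk study: TIFF images + sidecar JSON, PNG masks,
    manifest CSV, counts CSV, flow-events CSV and ground_truth.json."""
    import tifffile
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest_rows, counts_frames, event_frames = [], [], []
    truth: dict = {"conditions": {}}
    for donor, inducer in spec.conditions:
        n_images = max(1, spec.n_cells_per_condition // cells_per_image)
        cell_idx = 0
        for im in range(n_images):
            field_rng_tag = f"{donor}_{inducer}_{im:03d}"
            field = generate_cell_field(
                replace(spec, seed=spec.seed + im), donor, inducer,
                image_size=image_size, n_cells=cells_per_image)
            image_rel = f"images/{field_rng_tag}.tif"
            tifffile.imwrite(out / image_rel,
                             field.image.astype(np.float32))
            (out / image_rel).with_suffix(".json").write_text(json.dumps({
                "pixel_size_x_um": spec.pixel_size_um,
                "pixel_size_y_um": spec.pixel_size_um}))
            for k, mask in enumerate(field.masks):
                mask_rel = f"masks/{field_rng_tag}_c{k}.png"
                Image.fromarray((mask * 255).astype(np.uint8)).save(out / mask_rel)
                manifest_rows.append({
                    "image_path": image_rel, "mask_path": mask_rel,
                    "donor": donor, "inducer": inducer,
                    "cell_id": f"{donor}:{inducer}:c{cell_idx}"})
                cell_idx += 1
        counts, events, cond_truth = generate_count_tables(spec, donor, inducer)
        counts_frames.append(counts)
        event_frames.append(pd.DataFrame({
            "condition": f"{donor}:{inducer}", "intensity": events}))
        truth["conditions"][f"{donor}:{inducer}"] = cond_truth
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    pd.concat(counts_frames, ignore_index=True).to_csv(
        out / "counts.csv", index=False)
    pd.concat(event_frames, ignore_index=True).to_csv(
        out / "flow_events.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return out
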
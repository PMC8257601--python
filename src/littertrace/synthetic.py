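"""Forward simulation of a 13C litter-tracing microcosm experiment.

Every input the analysis consumes — headspace gas tables, OM-fraction
tables, FAME tables, NMR spectra, NanoSIMS ion-image stacks — can be
generated here with known ground truth, so each pipeline stage is
testable end to end without laboratory data.

The default scenario mirrors the study design the package targets: two
soil textures (coarse, fine) crossed with litter addition (13C-labeled
maize, delta13C = 2129 permil) versus control, five replicates, twelve
sampling days over a 95-day incubation, three depth increments, five
physical OM fractions, the conventional PLFA marker set, and 25x25 um
NanoSIMS acquisitions of 40 planes at 1 ms dwell.

Source fluxes follow a two-pool (fast + slow) exponential decay per
source; priming is a multiplicative factor on the basal soil flux in
litter treatments. Mixture delta13C values are composed with the same
linear two-pool mixing the analysis inverts, so noiseless generation
followed by the full pipeline recovers the ground truth exactly — the
module's core contract. Measurement noise is Gaussian (concentrations,
delta values, NMR intensity) or Poisson (ion counts).

All generators are pure functions of (config, seed): regeneration with
the same seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import nanosims, plfa
from .isotope import delta_to_atom_fraction, atom_fraction_to_delta
from .nmr import MMM_REGIONS, SignatureMatrix, load_signatures
from .respiration import RespirationConfig, _integrate_rates

__all__ = [
    "ScenarioConfig",
    "gen_respiration",
    "gen_fractions",
    "gen_fame",
    "gen_nmr",
    "gen_ion_stacks",
    "gen_experiment",
    "simulate_roi_counts",
]

SAMPLING_DAYS = (2, 3, 4, 8, 10, 15, 23, 31, 44, 65, 80, 95)
DEPTHS = ("top", "center", "bottom")
TEXTURES = ("coarse", "fine")


@dataclass
class ScenarioConfig:
    """Parameters of the simulated microcosm experiment.

    Flux-model amplitudes are mg CO2-C per day per g C_bulk; rates are
    per day. The default magnitudes place litter share of respiration
    near 30% and hyphal labeling near 3 atom % so synthetic output is
    visually comparable to the real study, without asserting equality.
    """

    textures: tuple = TEXTURES
    n_replicates: int = 5
    sampling_days: tuple = SAMPLING_DAYS
    delta_litter: float = 2129.0
    delta_soil: float = -28.0

    # respiration: per-texture two-pool source fluxes (fast amp, fast
    # rate, slow amp, slow rate), mg CO2-C d-1 (g C_bulk)-1 and d-1
    soil_flux: dict = field(
        default_factory=lambda: {
            "coarse": (2.0, 0.08, 0.47, 0.002),
            "fine": (1.35, 0.08, 0.32, 0.002),
        }
    )
    litter_flux: dict = field(
        default_factory=lambda: {
            "coarse": (3.6, 0.10, 0.05, 0.002),
            "fine": (2.2, 0.10, 0.03, 0.002),
        }
    )
    priming_multiplier: dict = field(default_factory=lambda: {"coarse": 1.35, "fine": 1.24})
    c_bulk_g: dict = field(default_factory=lambda: {"coarse": 1.44, "fine": 1.80})
    v_headspace_ml: float = 377.0
    molar_volume_ml_mmol: float = 24.1
    ambient_co2_ppm: float = 420.0
    accumulation_min: float = 60.0
    co2_noise_ppm: float = 0.0
    delta_noise_permil: float = 0.0

    # fractions: per (fraction, depth) litter-derived C share in litter
    # treatments, %; masses g and C contents mg/g per fraction
    fraction_litter_pct: dict = field(
        default_factory=lambda: {
            "fPOM": {"top": 65.0, "center": 25.0, "bottom": 10.0},
            "oPOM": {"top": 40.0, "center": 15.0, "bottom": 6.0},
            "oPOM_small": {"top": 30.0, "center": 12.0, "bottom": 5.0},
            "sand_coarse_silt": {"top": 8.0, "center": 3.0, "bottom": 1.0},
            "MAOM": {"top": 6.0, "center": 2.5, "bottom": 1.0},
        }
    )
    fraction_mass_g: dict = field(
        default_factory=lambda: {
            "fPOM": 0.15,
            "oPOM": 0.25,
            "oPOM_small": 0.20,
            "sand_coarse_silt": 9.0,
            "MAOM": 9.0,
        }
    )
    fraction_c_mg_g: dict = field(
        default_factory=lambda: {
            "fPOM": 380.0,
            "oPOM": 300.0,
            "oPOM_small": 250.0,
            "sand_coarse_silt": 3.0,
            "MAOM": 18.0,
        }
    )
    bulk_mass_g: float = 18.5
    c_loss: float = 0.0  # prescribed fractionation C/mass loss, 0..1
    fraction_delta_noise_permil: float = 0.0

    # PLFA: per-group atom-fraction excess of labeled FAs (top depth),
    # depth attenuation, and the share of each group's FAs that take up
    # label; fungi highest by design
    plfa_group_excess: dict = field(
        default_factory=lambda: {
            "fungi": 4.0e-3,
            "gram_negative": 1.5e-3,
            "gram_positive": 8.0e-4,
            "general_bacteria": 1.2e-3,
        }
    )
    plfa_labeled_fraction: dict = field(
        default_factory=lambda: {
            "fungi": 1.0,
            "gram_negative": 1.0,
            "gram_positive": 0.5,
            "general_bacteria": 0.5,
        }
    )
    plfa_group_conc: dict = field(
        default_factory=lambda: {
            "fungi": 18.0,
            "gram_negative": 30.0,
            "gram_positive": 24.0,
            "general_bacteria": 40.0,
        }
    )
    plfa_depth_factor: dict = field(
        default_factory=lambda: {"top": 1.0, "center": 0.45, "bottom": 0.25}
    )
    plfa_n_replicates: int = 3
    plfa_delta_noise_permil: float = 0.0
    c_bulk_mg_g: dict = field(default_factory=lambda: {"coarse": 12.0, "fine": 20.0})

    # NMR
    nmr_ppm_range: tuple = (-10.0, 225.0)
    nmr_ppm_step: float = 0.05
    nmr_peak_width_divisor: float = 12.0

    # NanoSIMS: per-region (total C counts per pixel-plane, CN counts,
    # 13C atom fraction); geometry scaled to 64 px for fast simulation
    sims_shape: tuple = (64, 64)
    sims_n_planes: int = 40
    sims_dwell_s: float = 1e-3
    sims_dead_time_s: float = 44e-9
    sims_regions: dict = field(
        default_factory=lambda: {
            "POM": (90.0, 40.0, 0.015),
            "hyphae": (110.0, 70.0, 0.030),
            "bacteria": (100.0, 80.0, 0.023),
            "EPS": (95.0, 95.0, 0.030),
            "mineral": (4.0, 1.0, 0.011),
        }
    )

    master_seed: int = 0


def _rng(seed, stream: int) -> np.random.Generator:
    """Deterministic child generator for one output stream."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def _two_pool_rate(t_days: np.ndarray, params: tuple) -> np.ndarray:
    a1, k1, a2, k2 = params
    return a1 * np.exp(-k1 * t_days) + a2 * np.exp(-k2 * t_days)


def gen_respiration(cfg: ScenarioConfig, seed: int | None = None):
    """Simulate the headspace gas table for all microcosms.

    Returns ``(gas_df, truth)``. The truth dict records, per texture:
    true per-day litter fraction, true cumulative litter/soil CO2-C per
    g C_bulk (under the same trapezoidal accumulation the analysis
    uses), and the true priming trajectory.
    """
    seed = cfg.master_seed if seed is None else seed
    rng = _rng(seed, 0)
    days = np.asarray(cfg.sampling_days, dtype=float)
    rows = []
    truth: dict = {"per_texture": {}}
    for texture in cfg.textures:
        c_bulk = cfg.c_bulk_g[texture]
        soil_rate_gc = _two_pool_rate(days, cfg.soil_flux[texture])  # mg/d/gC
        litter_rate_gc = _two_pool_rate(days, cfg.litter_flux[texture])
        m = cfg.priming_multiplier[texture]
        # litter treatment: primed soil + litter source; control: basal soil
        treat_soil = soil_rate_gc * m
        frac_litter = litter_rate_gc / (treat_soil + litter_rate_gc)
        hours = days * 24.0
        cum_litter = _integrate_rates(hours, litter_rate_gc / 24.0)
        cum_soil_primed = _integrate_rates(hours, treat_soil / 24.0)
        cum_control = _integrate_rates(hours, soil_rate_gc / 24.0)
        truth["per_texture"][texture] = {
            "days": days.tolist(),
            "litter_fraction": frac_litter.tolist(),
            "cum_litter_mg_gC": cum_litter.tolist(),
            "cum_soil_mg_gC": cum_soil_primed.tolist(),
            "cum_control_mg_gC": cum_control.tolist(),
            "priming_mg_gC": (cum_soil_primed - cum_control).tolist(),
            "c_bulk_g": c_bulk,
        }
        for treatment in ("litter", "control"):
            for rep in range(1, cfg.n_replicates + 1):
                mc_id = f"{texture}_{treatment}_{rep}"
                for j, day in enumerate(days):
                    if treatment == "litter":
                        rate_gc = treat_soil[j] + litter_rate_gc[j]
                        f_lit = frac_litter[j]
                    else:
                        rate_gc = soil_rate_gc[j]
                        f_lit = 0.0
                    flux_mg_h = rate_gc * c_bulk / 24.0
                    dppm = (
                        flux_mg_h
                        * cfg.accumulation_min
                        / (1e-6 * (cfg.v_headspace_ml / cfg.molar_volume_ml_mmol) * 12.0 * 60.0)
                    )
                    delta_resp = f_lit * cfg.delta_litter + (1.0 - f_lit) * cfg.delta_soil
                    if cfg.co2_noise_ppm > 0:
                        dppm += rng.normal(0.0, cfg.co2_noise_ppm)
                    if cfg.delta_noise_permil > 0:
                        delta_resp += rng.normal(0.0, cfg.delta_noise_permil)
                    rows.append(
                        {
                            "microcosm_id": mc_id,
                            "treatment": treatment,
                            "texture": texture,
                            "day": int(day),
                            "t_start_min": 0.0,
                            "t_end_min": cfg.accumulation_min,
                            "co2_start_ppm": cfg.ambient_co2_ppm,
                            "co2_end_ppm": cfg.ambient_co2_ppm + dppm,
                            "delta13c_resp_permil": delta_resp,
                        }
                    )
    return pd.DataFrame(rows), truth


def respiration_config(cfg: ScenarioConfig, texture: str) -> RespirationConfig:
    """Analysis config matching the generator's constants for one texture."""
    return RespirationConfig(
        v_headspace_ml=cfg.v_headspace_ml,
        molar_volume_ml_mmol=cfg.molar_volume_ml_mmol,
        c_bulk_mass_g=cfg.c_bulk_g[texture],
        delta_litter=cfg.delta_litter,
        delta_control=cfg.delta_soil,
    )


def gen_fractions(cfg: ScenarioConfig, seed: int | None = None):
    """Simulate the OM-fraction table (litter treatments plus controls).

    Per fraction x depth the litter-derived C share is prescribed; the
    fraction's delta13C is composed by exact two-pool mixing. A
    prescribed ``c_loss`` shrinks recovered masses so recovery checks
    read (1 - c_loss). Truth records litter %, litter C mass, and the
    per-g-C_bulk allocation per texture/depth/fraction.
    """
    seed = cfg.master_seed if seed is None else seed
    rng = _rng(seed, 1)
    rows, truth_records = [], []
    keep = 1.0 - cfg.c_loss
    for texture in cfg.textures:
        for treatment in ("litter", "control"):
            for depth in DEPTHS:
                bulk_c_mg = sum(
                    cfg.fraction_mass_g[f] * cfg.fraction_c_mg_g[f] for f in cfg.fraction_litter_pct
                )
                for rep in range(1, cfg.plfa_n_replicates + 1):
                    for frac_id, per_depth in cfg.fraction_litter_pct.items():
                        pct = per_depth[depth] if treatment == "litter" else 0.0
                        mass = cfg.fraction_mass_g[frac_id] * keep
                        c_mg_g = cfg.fraction_c_mg_g[frac_id]
                        delta = (
                            pct / 100.0 * cfg.delta_litter + (1.0 - pct / 100.0) * cfg.delta_soil
                        )
                        if cfg.fraction_delta_noise_permil > 0:
                            delta += rng.normal(0.0, cfg.fraction_delta_noise_permil)
                        rows.append(
                            {
                                "fraction_id": frac_id,
                                "texture": texture,
                                "depth": depth,
                                "treatment": treatment,
                                "replicate": rep,
                                "mass_recovered_g": mass,
                                "c_content_mg_g": c_mg_g,
                                "n_content_mg_g": c_mg_g / 12.0,
                                "delta13c_permil": delta,
                            }
                        )
                        truth_records.append(
                            {
                                "texture": texture,
                                "treatment": treatment,
                                "depth": depth,
                                "replicate": rep,
                                "fraction_id": frac_id,
                                "litter_pct": pct,
                                "c_total_mg": c_mg_g * mass,
                                "c_litter_mg": pct / 100.0 * c_mg_g * mass,
                                "bulk_c_mg": bulk_c_mg,
                            }
                        )
    truth = {
        "records": truth_records,
        "bulk_mass_g": cfg.bulk_mass_g,
        "c_loss": cfg.c_loss,
        "expected_recovery_pct": 100.0 * keep,
    }
    return pd.DataFrame(rows), truth


def gen_fame(cfg: ScenarioConfig, seed: int | None = None):
    """Simulate the FAME table with group-specific label uptake.

    delta13C_FAME values are produced through the forward methylation
    model, so the methanol correction inverts them exactly. Within each
    group only the configured share of fatty acids takes up label;
    control samples sit at natural abundance with a deterministic
    per-FA offset so matched-control statistics are exercised.
    """
    seed = cfg.master_seed if seed is None else seed
    rng = _rng(seed, 2)
    by_group: dict[str, list] = {}
    for fa, grp in plfa.DEFAULT_MARKER_MAP.items():
        by_group.setdefault(grp, []).append(fa)
    fa_cn = {fa: _fa_carbon_number(fa) for fa in plfa.DEFAULT_MARKER_MAP}
    # deterministic small per-FA natural-abundance offsets (permil)
    fa_offsets = {
        fa: round(2.0 * np.sin(7.0 * i + 1.0), 3)
        for i, fa in enumerate(sorted(plfa.DEFAULT_MARKER_MAP))
    }
    rows, truth_groups = [], []
    for texture in cfg.textures:
        for depth in DEPTHS:
            depth_f = cfg.plfa_depth_factor[depth]
            for treatment in ("litter", "control"):
                for rep in range(1, cfg.plfa_n_replicates + 1):
                    for group, fas in by_group.items():
                        n_labeled = int(round(cfg.plfa_labeled_fraction[group] * len(fas)))
                        for idx, fa in enumerate(sorted(fas)):
                            conc = cfg.plfa_group_conc[group] * depth_f / len(fas)
                            base_delta = cfg.delta_soil + fa_offsets[fa]
                            labeled = treatment == "litter" and idx < n_labeled
                            if labeled:
                                af = delta_to_atom_fraction(base_delta) + cfg.plfa_group_excess[group]
                                delta_fa = atom_fraction_to_delta(af)
                            else:
                                delta_fa = base_delta
                            if cfg.plfa_delta_noise_permil > 0:
                                delta_fa += rng.normal(0.0, cfg.plfa_delta_noise_permil)
                            delta_fame = plfa.methylate_delta(delta_fa, fa_cn[fa])
                            rows.append(
                                {
                                    "texture": texture,
                                    "depth": depth,
                                    "treatment": treatment,
                                    "replicate": rep,
                                    "fa_name": fa,
                                    "c_n": fa_cn[fa],
                                    "conc_nmol_g": conc,
                                    "delta13c_fame_permil": delta_fame,
                                }
                            )
            # per-sample group truth (litter treatment, noiseless metrics)
            total_excess_mass = sum(
                cfg.plfa_group_conc[g]
                * depth_f
                * _labeled_share(cfg, g)
                * cfg.plfa_group_excess[g]
                for g in by_group
            )
            for group in by_group:
                lab_share = _labeled_share(cfg, group)
                conc_g = cfg.plfa_group_conc[group] * depth_f
                excess_mass = conc_g * lab_share * cfg.plfa_group_excess[group]
                truth_groups.append(
                    {
                        "texture": texture,
                        "depth": depth,
                        "group": group,
                        "total_plfa_nmol_g": conc_g,
                        "within_group_enriched_pct": 100.0 * lab_share,
                        "rel_incorporation_pct": 100.0 * excess_mass / total_excess_mass,
                    }
                )
    truth = {"groups": truth_groups, "c_bulk_mg_g": dict(cfg.c_bulk_mg_g)}
    return pd.DataFrame(rows), truth


def _labeled_share(cfg: ScenarioConfig, group: str) -> float:
    """Realised labeled share of a group after rounding to whole fatty acids."""
    fas = [fa for fa, g in plfa.DEFAULT_MARKER_MAP.items() if g == group]
    n_labeled = int(round(cfg.plfa_labeled_fraction[group] * len(fas)))
    return n_labeled / len(fas)


def _fa_carbon_number(fa_name: str) -> int:
    """Carbon number from a canonical fatty-acid label (e.g. iC15:0 -> 15)."""
    core = fa_name.lstrip("iaC").split(":")[0]
    if core == "":  # the literally-printed marker "C:17"
        core = fa_name.split(":")[1]
    return int(core)


def gen_nmr(
    composition: dict[str, float],
    seed: int = 0,
    *,
    noise: float = 0.0,
    signatures: SignatureMatrix | None = None,
    cfg: ScenarioConfig | None = None,
):
    """Simulate a CP-MAS spectrum for a compound-class composition.

    Each class contributes narrow Gaussian peaks centred in the MMM
    regions with areas matching its signature column, so the region
    integrals of a noiseless spectrum reproduce ``A @ x`` to numerical
    precision. ``noise`` is the per-point Gaussian sigma relative to
    the mean spectral intensity.
    """
    cfg = cfg or ScenarioConfig()
    sig = signatures if signatures is not None else load_signatures()
    x = np.array([composition.get(c, 0.0) for c in sig.classes], dtype=float)
    if np.any(x < 0) or not np.isclose(x.sum(), 1.0, atol=1e-9):
        raise ValueError("composition must be non-negative and sum to 1")
    lo, hi = cfg.nmr_ppm_range
    ppm = np.arange(lo, hi + cfg.nmr_ppm_step / 2, cfg.nmr_ppm_step)
    intensity = np.zeros_like(ppm)
    region_bounds = [MMM_REGIONS[r] for r in sig.regions]
    for j, frac in enumerate(x):
        if frac == 0:
            continue
        for (rlo, rhi), weight in zip(region_bounds, sig.matrix[:, j]):
            if weight == 0:
                continue
            centre = 0.5 * (rlo + rhi)
            sigma = (rhi - rlo) / cfg.nmr_peak_width_divisor
            area = frac * weight
            intensity += (
                area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((ppm - centre) / sigma) ** 2)
            )
    if noise > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise * intensity.mean(), size=intensity.shape)
    truth = {"composition": dict(zip(sig.classes, x.tolist()))}
    return ppm, intensity, truth


def _region_masks(shape: tuple, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Label map: hypha curve, bacterial discs, EPS patch, mineral grains, POM background."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    masks: dict[str, np.ndarray] = {}
    # fungal hypha: a thickened sine curve across the field
    cx = np.arange(w)
    cy = h * 0.3 + h * 0.12 * np.sin(2 * np.pi * cx / w * 1.7)
    hypha = np.zeros(shape, dtype=bool)
    for x0, y0 in zip(cx, cy):
        hypha |= (yy - y0) ** 2 + (xx - x0) ** 2 <= 2.2**2
    masks["hyphae"] = hypha
    # individual bacteria: small discs
    bact = np.zeros(shape, dtype=bool)
    for _ in range(6):
        bx, by = rng.integers(5, w - 5), rng.integers(int(h * 0.55), h - 5)
        bact |= (yy - by) ** 2 + (xx - bx) ** 2 <= 2.0**2
    masks["bacteria"] = bact & ~hypha
    # EPS patch: one larger blob
    ex, ey = int(w * 0.75), int(h * 0.25)
    eps = (yy - ey) ** 2 + (xx - ex) ** 2 <= (0.12 * w) ** 2
    masks["EPS"] = eps & ~hypha & ~bact
    # mineral grains
    mine = np.zeros(shape, dtype=bool)
    for _ in range(4):
        mx, my = rng.integers(3, w - 3), rng.integers(3, h - 3)
        mine |= (yy - my) ** 2 + (xx - mx) ** 2 <= 3.0**2
    taken = hypha | bact | eps
    masks["mineral"] = mine & ~taken
    masks["POM"] = ~(taken | masks["mineral"])
    return masks


def gen_ion_stacks(cfg: ScenarioConfig, seed: int | None = None, *, drift: bool = False):
    """Simulate a NanoSIMS acquisition with labeled biological regions.

    Per-region expected count rates pass through the forward dead-time
    model before per-plane Poisson draws, so the analysis-side
    correction is exercised. With ``drift`` the planes are shifted by a
    known integer walk, recorded in the truth dict.

    Returns ``(stack, masks, truth)``.
    """
    seed = cfg.master_seed if seed is None else seed
    rng = _rng(seed, 3)
    shape = tuple(cfg.sims_shape)
    masks = _region_masks(shape, rng)
    c_rate = np.zeros(shape)
    cn_rate = np.zeros(shape)
    af = np.zeros(shape)
    for region, (c_total, cn, region_af) in cfg.sims_regions.items():
        m = masks[region]
        c_rate[m] = c_total
        cn_rate[m] = cn
        af[m] = region_af
    exp = {
        "12C": c_rate * (1.0 - af),
        "13C": c_rate * af,
        "12C14N": cn_rate,
        "16O": np.where(masks["mineral"], 150.0, 15.0),
    }
    shifts = [(0, 0)]
    if drift:
        for _ in range(cfg.sims_n_planes - 1):
            dy = int(np.clip(shifts[-1][0] + rng.integers(-1, 2), -3, 3))
            dx = int(np.clip(shifts[-1][1] + rng.integers(-1, 2), -3, 3))
            shifts.append((dy, dx))
    counts = {}
    for sp, rate in exp.items():
        measured_rate = nanosims.dead_time_forward(rate, cfg.sims_dwell_s, cfg.sims_dead_time_s)
        planes = []
        for p in range(cfg.sims_n_planes):
            plane = rng.poisson(measured_rate)
            if drift and p > 0:
                plane = nanosims._shift_int(plane, *shifts[p])
            planes.append(plane)
        counts[sp] = np.stack(planes).astype(np.int64)
    stack = nanosims.IonImageStack(
        counts=counts,
        dwell_s=cfg.sims_dwell_s,
        dead_time_s=cfg.sims_dead_time_s,
        field_of_view_um=25.0,
    )
    truth = {
        "atom_fraction": {r: v[2] for r, v in cfg.sims_regions.items()},
        "c_rate": {r: v[0] for r, v in cfg.sims_regions.items()},
        "cn_rate": {r: v[1] for r, v in cfg.sims_regions.items()},
        "n_planes": cfg.sims_n_planes,
        "shifts": [list(s) for s in shifts] if drift else None,
    }
    return stack, masks, truth


def simulate_roi_counts(
    atom_fraction: float,
    *,
    n_pixels: int = 200,
    n_planes: int = 40,
    c_rate: float = 100.0,
    cn_rate: float = 60.0,
    dwell_s: float = 1e-3,
    dead_time_s: float = 44e-9,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Poisson ROI counts at a true 13C atom fraction, dead-time thinned.

    Returns accumulated (summed over planes), dead-time-corrected
    images of shape (n_pixels,), ready for :func:`~littertrace.nanosims.roi_ratios`.
    """
    rates = {
        "12C": c_rate * (1.0 - atom_fraction),
        "13C": c_rate * atom_fraction,
        "12C14N": cn_rate,
    }
    images = {}
    for sp, rate in rates.items():
        thinned = nanosims.dead_time_forward(rate, dwell_s, dead_time_s)
        raw = rng.poisson(thinned, size=(n_planes, n_pixels))
        corrected = nanosims.dead_time_correct(raw, dwell_s, dead_time_s)
        images[sp] = corrected.sum(axis=0)
    return images


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def gen_experiment(cfg: ScenarioConfig, out_dir: str | Path) -> dict:
    """Generate the full coherent bundle into a directory.

    Writes gas/fraction/FAME CSVs, one NMR spectrum per POM fraction
    composition, NanoSIMS TIFF stacks with ROI masks, a ``truth.json``
    with every generator's ground truth, and a ``manifest.json``
    listing each file with its SHA-256 checksum.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth: dict = {"config": {"master_seed": cfg.master_seed}}

    gas, truth["respiration"] = gen_respiration(cfg)
    gas.to_csv(out / "gas.csv", index=False)
    fracs, truth["fractions"] = gen_fractions(cfg)
    fracs.to_csv(out / "fractions.csv", index=False)
    fame, truth["plfa"] = gen_fame(cfg)
    fame.to_csv(out / "fame.csv", index=False)

    compositions = {
        "fPOM_litter": {"carbohydrate": 0.60, "protein": 0.10, "lignin": 0.20, "lipid": 0.10},
        "oPOM_control": {"carbohydrate": 0.40, "protein": 0.12, "lignin": 0.33, "lipid": 0.15},
    }
    truth["nmr"] = {}
    for name, comp in compositions.items():
        full = {c: comp.get(c, 0.0) for c in ("carbohydrate", "protein", "lignin", "lipid", "carbonyl", "char")}
        ppm, inten, t = gen_nmr(full, seed=cfg.master_seed)
        np.savetxt(out / f"nmr_{name}.txt", np.column_stack([ppm, inten]), fmt="%.6g")
        truth["nmr"][name] = t

    stack, masks, truth["nanosims"] = gen_ion_stacks(cfg)
    nanosims.write_stack_dir(stack, out / "sims")
    for region, mask in masks.items():
        tifffile.imwrite(out / "sims" / f"mask_{region}.tif", mask.astype(np.uint8))

    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    manifest = {
        p.name: _sha256(p) for p in sorted(out.rglob("*")) if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
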
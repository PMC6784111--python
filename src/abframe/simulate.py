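"""Seeded generators for every input the analysis pipeline consumes.

Each generator plants a ground truth mirroring the study's effect sizes and
emits it alongside the data, so recovery tests compare fitted values against
known truths:

* variant panel: a toy kappa germline set with a parental VL differing from
  its closest germline at five framework positions in three groupable
  regions (1-4, 66, 79) -> the 2^3 combination panel plus the
  lysine-bearing parental duplicate (9 entries);
* binding kinetics: per-variant (ka, kd) planted at the reported values
  (ka 1.1-3.1 x 10^5 /M/s, kd 2.9-6.4 x 10^-4 /s), all KD within a factor
  of two of the parental;
* thermal stability: Tm offsets of ~0, +0.5, +2 and +4 degC keyed to the
  germlined region content (Q79E drives the +2 degC class; combining region
  1-4 with A66G is synergistic);
* expression: titer fold-effects of 3-10x for A66G-containing variants,
  lognormal replicates (CV 20%, five expression runs);
* aggregation: monomer fraction ~0.97 (optimized) vs ~0.89 (parental) with
  a slow decline over 12 weeks at 4 degC;
* pharmacokinetics: two-compartment truths taken from the reported fit
  parameters per antibody x dose (distribution half-life 5 h), n = 4
  animals, multiplicative lognormal noise, LOQ censoring that suppresses
  the parental low-dose tail beyond 48 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dsf import MeltCurve, simulate_melt_curve
from .germline import (
    MutationRegion,
    VariantPanel,
    enumerate_variants,
    find_closest_germline,
    group_mismatches,
    load_toy_germlines,
)
from .kabat import CONSENSUS_TEMPLATES, NumberedSequence, assign_kabat_numbering
from .pk import PKDataset, censor_loq
from .sec import ChromatogramTrace, simulate_chromatogram
from .spr import Sensorgram, simulate_sensorgram

# ---------------------------------------------------------------------------
# planted truths (study conditions)

PARENTAL_NAME = "1-DIQMAQ"
PARENTAL_K_NAME = "2-DIQMAQ-K"
OPTIMIZED_NAME = "9-EIVLGE"

# per-variant binding truths: (ka /M/s, kd /s), the reported panel values
KINETIC_TRUTHS: Dict[str, Tuple[float, float]] = {
    "DIQMAQ": (1.1e5, 2.9e-4),
    "DIQMAQ-K": (1.3e5, 3.8e-4),
    "EIVLAQ": (2.0e5, 3.1e-4),
    "DIQMGQ": (1.6e5, 5.6e-4),
    "DIQMAE": (1.6e5, 4.0e-4),
    "EIVLGQ": (2.6e5, 6.4e-4),
    "EIVLAE": (1.8e5, 4.4e-4),
    "DIQMGE": (1.3e5, 5.4e-4),
    "EIVLGE": (3.1e5, 4.4e-4),
}

PARENTAL_TM_C = 70.0
# Tm offsets keyed to germlined-region content: Q79E (third letter E of the
# second triplet) gives the >2 degC class; 1-4 x A66G combinations are
# synergistic (>4 degC)
TM_OFFSETS_C: Dict[str, float] = {
    "DIQMAQ": 0.0, "DIQMAQ-K": 0.0,
    "EIVLAQ": 0.5, "DIQMGQ": 0.7, "DIQMAE": 2.2,
    "EIVLAE": 2.3, "DIQMGE": 2.4,
    "EIVLGQ": 4.1, "EIVLGE": 4.3,
}

PARENTAL_TITER_MG_L = 100.0
# titer fold-effects vs parental: only A66G-containing variants (G at the
# middle signature position) rise 3-10x
TITER_FOLDS: Dict[str, float] = {
    "DIQMAQ": 1.0, "DIQMAQ-K": 1.0,
    "EIVLAQ": 1.3, "DIQMGQ": 4.0, "DIQMAE": 1.2,
    "EIVLGQ": 7.0, "EIVLAE": 1.4, "DIQMGE": 5.0,
    "EIVLGE": 10.0,
}

# SEC monomer fractions at week 0 and week 12 (linear decline between)
MONOMER_COURSE: Dict[str, Tuple[float, float]] = {
    PARENTAL_K_NAME: (0.890, 0.850),
    OPTIMIZED_NAME: (0.974, 0.956),
}
SEC_WEEKS = (0.0, 2.0, 4.0, 8.0, 12.0)
SEC_RETENTION_MIN = {"aggregate": 5.4, "dimer": 6.5, "monomer": 7.6, "fragment": 9.0}
SEC_WIDTHS_MIN = {"aggregate": 0.12, "dimer": 0.10, "monomer": 0.10, "fragment": 0.12}

# two-compartment PK truths per (antibody, dose): C0_alpha, C0_beta (mg/L),
# terminal half-life (h); the parental 5 mg/kg arm is dose-scaled from its
# 15 mg/kg fit (the study could not estimate it: censored beyond 48 h)
PK_TRUTHS: Dict[Tuple[str, float], Tuple[float, float, float]] = {
    (PARENTAL_K_NAME, 5.0): (2.0, 1.2333, 34.5),
    (PARENTAL_K_NAME, 15.0): (6.0, 3.7, 34.5),
    (PARENTAL_K_NAME, 30.0): (15.6, 5.0, 37.9),
    (OPTIMIZED_NAME, 5.0): (29.7, 14.0, 135.9),
    (OPTIMIZED_NAME, 15.0): (76.4, 45.1, 96.3),
    (OPTIMIZED_NAME, 30.0): (149.1, 55.2, 87.7),
}
PK_SAMPLING_TIMES_H = (0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0)


@dataclass
class GeneratorConfig:
    seed: int = 0
    # binding kinetics
    spr_concentrations_m: Sequence[float] = (3e-9, 6e-9, 12e-9, 18e-9, 25e-9)
    spr_rmax_ru: float = 40.0
    spr_t_stop_s: float = 300.0
    spr_t_max_s: float = 1500.0
    spr_noise_sd_ru: float = 0.5
    # thermal stability
    dsf_grid_c: Tuple[float, float, float] = (25.0, 95.0, 0.5)  # start, stop, step
    dsf_slope_c: float = 1.5
    dsf_amplitude: float = 1000.0
    dsf_noise_frac: float = 0.01   # of amplitude
    # expression
    titer_replicates: int = 5
    titer_cv: float = 0.20
    # aggregation
    sec_noise_frac: float = 0.005  # of trace maximum
    # pharmacokinetics
    pk_doses_mg_per_kg: Sequence[float] = (5.0, 15.0, 30.0)
    pk_times_h: Sequence[float] = PK_SAMPLING_TIMES_H
    pk_n_animals: int = 4
    pk_noise_cv: float = 0.20
    pk_loq_mg_per_l: float = 0.4
    pk_t_half_alpha_h: float = 5.0

    def __post_init__(self):
        # normalize sequence fields so configs round-trip serialization
        self.spr_concentrations_m = tuple(self.spr_concentrations_m)
        self.dsf_grid_c = tuple(self.dsf_grid_c)
        self.pk_doses_mg_per_kg = tuple(self.pk_doses_mg_per_kg)
        self.pk_times_h = tuple(self.pk_times_h)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# variant panel


@dataclass
class PanelBundle:
    germlines: List[NumberedSequence]
    parental: NumberedSequence
    match: object                    # GermlineMatch
    regions: List[MutationRegion]
    panel: VariantPanel


def parental_vl_sequence() -> str:
    """The parental kappa VL: consensus framework carrying A66 (and Q79)."""
    seq = list(CONSENSUS_TEMPLATES["L"])
    seq[65] = "A"  # Kabat 66, insertion-free template
    return "".join(seq)


def generate_variant_panel(
    config: GeneratorConfig,
    mutation_positions: Optional[Sequence[int]] = None,
) -> PanelBundle:
    """Toy germline set, parental VL and the enumerated variant panel.

    With the default (study-like) design the parental carries five planted
    framework mismatches in three groupable regions and the panel has the
    nine entries of the reported scheme. `mutation_positions` overrides the
    planted mismatch positions (empty -> panel of size 1).
    """
    germlines = load_toy_germlines("L")
    parental = assign_kabat_numbering(parental_vl_sequence(), "L")
    parental.source_id = "parental-VL"

    match = find_closest_germline(parental, germlines)
    germ = next(g for g in germlines if g.source_id == match.germline_id)

    mismatches = match.mismatches
    if mutation_positions is not None:
        wanted = set(mutation_positions)
        mismatches = [m for m in mismatches if m[0].number in wanted]
    regions = group_mismatches(mismatches, query=parental, germline=germ)
    if not regions:
        panel = VariantPanel(parental_name=PARENTAL_NAME, regions=[], variants=[])
        # degenerate request: a panel of just the parental
        from .germline import VariantRecord
        panel.variants.append(VariantRecord(1, "DIQMAQ", (), False, parental))
        return PanelBundle(germlines, parental, match, [], panel)
    panel = enumerate_variants(parental, regions, include_lysine_parental=True)
    return PanelBundle(germlines, parental, match, regions, panel)


# ---------------------------------------------------------------------------
# assay suite


@dataclass
class AssaySuite:
    truth: pd.DataFrame                              # per-variant planted truth
    sensorgrams: Dict[str, List[Sensorgram]]
    melt_curves: Dict[str, MeltCurve]
    titers: Dict[str, np.ndarray]
    chromatograms: Dict[str, List[Tuple[float, ChromatogramTrace]]]  # (week, trace)


def _sec_areas(monomer_frac: float, fragment_frac: float = 0.03) -> Dict[str, float]:
    rest = 1.0 - monomer_frac - fragment_frac
    return {
        "aggregate": 0.4 * rest,
        "dimer": 0.6 * rest,
        "monomer": monomer_frac,
        "fragment": fragment_frac,
    }


def generate_assay_suite(config: GeneratorConfig, panel: VariantPanel) -> AssaySuite:
    """Sensorgrams, melt curves, titers and SEC traces with planted truths."""
    if not panel.variants:
        raise ValueError("panel is empty")
    rng_spr = _rng(config, 1)
    rng_dsf = _rng(config, 2)
    rng_titer = _rng(config, 3)
    rng_sec = _rng(config, 4)

    t_assoc = np.arange(1.0, config.spr_t_stop_s + 1e-9, 2.0)
    t_dissoc = np.arange(config.spr_t_stop_s + 2.0, config.spr_t_max_s + 1e-9, 2.0)
    spr_times = np.concatenate([t_assoc, t_dissoc])
    start, stop, step = config.dsf_grid_c
    dsf_grid = np.arange(start, stop + 1e-9, step)

    rows = []
    sensorgrams: Dict[str, List[Sensorgram]] = {}
    melt_curves: Dict[str, MeltCurve] = {}
    titers: Dict[str, np.ndarray] = {}
    chromatograms: Dict[str, List[Tuple[float, ChromatogramTrace]]] = {}

    for variant in panel.variants:
        name = variant.name
        ka, kd = KINETIC_TRUTHS[name]
        tm = PARENTAL_TM_C + TM_OFFSETS_C[name]
        titer_mean = PARENTAL_TITER_MG_L * TITER_FOLDS[name]

        sensorgrams[name] = simulate_sensorgram(
            ka, kd, config.spr_rmax_ru, config.spr_concentrations_m,
            spr_times, config.spr_t_stop_s,
            noise_sd=config.spr_noise_sd_ru, rng=rng_spr,
        )
        amp = config.dsf_amplitude
        melt_curves[name] = simulate_melt_curve(
            tm, config.dsf_slope_c,
            pre_baseline=(1000.0, -2.0), post_baseline=(1000.0 + amp, -5.0),
            grid=dsf_grid, noise_sd=config.dsf_noise_frac * amp, rng=rng_dsf,
        )
        # lognormal replicates with the planted mean: mu chosen so that
        # E[titer] = titer_mean at the configured CV
        sigma = np.sqrt(np.log(1.0 + config.titer_cv**2))
        mu = np.log(titer_mean) - sigma**2 / 2.0
        titers[name] = rng_titer.lognormal(mu, sigma, size=config.titer_replicates)

        rows.append({
            "name": name, "full_name": f"{variant.id}-{name}",
            "ka_per_m_s": ka, "kd_per_s": kd, "kD_m": kd / ka,
            "tm_c": tm, "titer_mean_mg_l": titer_mean,
        })

    for name, (m0, m12) in MONOMER_COURSE.items():
        short = name.split("-", 1)[1]
        course = []
        for week in SEC_WEEKS:
            mono = m0 + (m12 - m0) * week / SEC_WEEKS[-1]
            trace, _ = simulate_chromatogram(
                _sec_areas(mono), SEC_RETENTION_MIN, SEC_WIDTHS_MIN,
                baseline=(0.5, 0.05),
                noise_sd=config.sec_noise_frac * _sec_peak_height(mono),
                rng=rng_sec,
            )
            course.append((week, trace))
        chromatograms[short] = course

    truth = pd.DataFrame(rows).set_index("name")
    return AssaySuite(truth=truth, sensorgrams=sensorgrams,
                      melt_curves=melt_curves, titers=titers,
                      chromatograms=chromatograms)


def _sec_peak_height(monomer_frac: float) -> float:
    w = SEC_WIDTHS_MIN["monomer"]
    return monomer_frac / (w * np.sqrt(2 * np.pi))


# ---------------------------------------------------------------------------
# pharmacokinetic study


def biexponential_truth(
    antibody: str, dose: float, t_half_alpha_h: float = 5.0
) -> Dict[str, float]:
    """Generating two-compartment parameters for one study arm."""
    c0a, c0b, t_half_beta = PK_TRUTHS[(antibody, dose)]
    return {
        "c0_alpha": c0a,
        "alpha": np.log(2.0) / t_half_alpha_h,
        "c0_beta": c0b,
        "beta": np.log(2.0) / t_half_beta,
        "t_half_beta": t_half_beta,
    }


def simulate_pk_arm(
    antibody: str,
    dose: float,
    times: Sequence[float],
    n_animals: int,
    noise_cv: float,
    rng: np.random.Generator,
    t_half_alpha_h: float = 5.0,
    loq: Optional[float] = None,
) -> PKDataset:
    """Simulate one antibody x dose arm with lognormal multiplicative noise."""
    p = biexponential_truth(antibody, dose, t_half_alpha_h)
    t = np.asarray(times, dtype=float)
    mean = p["c0_alpha"] * np.exp(-p["alpha"] * t) + p["c0_beta"] * np.exp(-p["beta"] * t)
    if noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + noise_cv**2))
        noise = rng.lognormal(-sigma**2 / 2.0, sigma, size=(n_animals, len(t)))
    else:
        noise = np.ones((n_animals, len(t)))
    conc = mean[None, :] * noise
    data = PKDataset(antibody_id=antibody, dose_mg_per_kg=dose,
                     times=t, concentrations=conc)
    if loq is not None:
        data = censor_loq(data, loq)
    return data


def generate_pk_study(config: GeneratorConfig) -> Dict[Tuple[str, float], PKDataset]:
    """All six antibody x dose arms with LOQ censoring applied."""
    rng = _rng(config, 5)
    study = {}
    for antibody in (PARENTAL_K_NAME, OPTIMIZED_NAME):
        for dose in config.pk_doses_mg_per_kg:
            study[(antibody, dose)] = simulate_pk_arm(
                antibody, dose, config.pk_times_h, config.pk_n_animals,
                config.pk_noise_cv, rng,
                t_half_alpha_h=config.pk_t_half_alpha_h,
                loq=config.pk_loq_mg_per_l,
            )
    return study
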
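"""Synthetic-data generators emulating the statistical structure of a
community-science starter survey, so every pipeline stage can be
exercised end-to-end without external downloads.

Three generators cover the survey (community table + metadata +
coordinates, with planted co-occurrence pairs, indicator effects and an
optional distance-decay geography), the serial-transfer competition
experiment (CFU counts realizing prescribed outcomes), and the
functional assays (rise curves, VOC profiles, blanks and sensory notes
driven by the acetic-acid-bacteria fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityTable
from .biogeography import GeoCoordinates
from .competition import (
    CO_PERSISTENCE,
    EXCLUSION_A,
    EXCLUSION_B,
    CompetitionDataset,
    pairwise_design,
)
from .kinetics import DEFAULT_TUBE_MM, logistic_curve
from .voc_function import VOCTable

__all__ = [
    "TaxonSpec",
    "PlantedPair",
    "IndicatorEffect",
    "SurveySpec",
    "FunctionSpec",
    "SurveyData",
    "FunctionData",
    "default_roster",
    "generate_survey",
    "example_competition_design",
    "generate_competitions",
    "generate_function",
]


@dataclass
class TaxonSpec:
    name: str
    kingdom: str
    group: str
    prevalence: float = 0.3
    dominance_weight: float = 0.0


@dataclass
class PlantedPair:
    taxon_a: str
    taxon_b: str
    sign: str  # positive | negative
    strength: float = 1.0


@dataclass
class IndicatorEffect:
    taxon: str
    variable: str
    level: str | None = None  # None => continuous slope effect
    presence_boost: float = 0.35
    abundance_multiplier: float = 4.0
    slope: float = 0.0  # presence-probability shift per SD (continuous)


@dataclass
class SurveySpec:
    n_samples: int = 500
    roster: list[TaxonSpec] = field(default_factory=lambda: default_roster())
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    aab_prevalence: float = 0.294  # ~147/500 samples containing AAB
    geography: str = "unstructured"  # or "decay"
    decay_rate: float = 0.0
    indicator_effects: list[IndicatorEffect] = field(default_factory=list)
    categorical_vars: dict[str, list[str]] = field(
        default_factory=lambda: {"grain_base": ["white", "whole_wheat", "rye"],
                                 "storage": ["counter", "fridge"]}
    )
    continuous_vars: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"age_years": (8.0, 6.0), "temperature_c": (12.0, 6.0)}
    )
    dirichlet_conc: float = 1.0
    dominance_alpha: float = 12.0
    abundance_floor: float = 0.02
    lat_range: tuple[float, float] = (25.0, 49.0)
    lon_range: tuple[float, float] = (-125.0, -67.0)
    seed: int = 0


@dataclass
class SurveyData:
    table: CommunityTable
    metadata: pd.DataFrame
    metadata_types: dict[str, str]
    coords: GeoCoordinates


def default_roster() -> list[TaxonSpec]:
    """A compact roster mirroring typical starter survey composition."""
    return [
        TaxonSpec("S_cerevisiae", "fungi", "yeast", 0.80, 0.55),
        TaxonSpec("K_humilis", "fungi", "yeast", 0.25, 0.25),
        TaxonSpec("K_servazzii", "fungi", "yeast", 0.15, 0.12),
        TaxonSpec("W_anomalus", "fungi", "yeast", 0.12, 0.08),
        TaxonSpec("L_sanfranciscensis", "bacteria", "LAB", 0.50, 0.40),
        TaxonSpec("L_plantarum", "bacteria", "LAB", 0.45, 0.30),
        TaxonSpec("L_brevis", "bacteria", "LAB", 0.35, 0.20),
        TaxonSpec("L_paralimentarius", "bacteria", "LAB", 0.20, 0.10),
        TaxonSpec("P_parvulus", "bacteria", "LAB", 0.10, 0.0),
        TaxonSpec("A_malorum", "bacteria", "AAB", 0.6, 0.0),
        TaxonSpec("G_frateurii", "bacteria", "AAB", 0.4, 0.0),
        TaxonSpec("Cladosporium_sp", "fungi", "other", 0.15, 0.0),
        TaxonSpec("Erwinia_sp", "bacteria", "other", 0.10, 0.0),
    ]


def _validate_planted(spec: SurveySpec) -> None:
    names = {t.name for t in spec.roster}
    seen: dict[frozenset, str] = {}
    for p in spec.planted_pairs:
        if p.taxon_a not in names or p.taxon_b not in names:
            raise ValueError(f"planted pair references unknown taxa: {p.taxon_a}, {p.taxon_b}")
        if p.sign not in ("positive", "negative"):
            raise ValueError(f"planted pair sign must be positive/negative, got {p.sign!r}")
        if not (0 <= p.strength <= 1):
            raise ValueError("planted pair strength must be in [0, 1]")
        key = frozenset((p.taxon_a, p.taxon_b))
        if key in seen and seen[key] != p.sign:
            raise ValueError(
                f"conflicting constraints for pair {sorted(key)}: a taxon cannot be "
                "simultaneously forced present with and absent from the same partner"
            )
        seen[key] = p.sign


def generate_survey(spec: SurveySpec, seed: int | None = None) -> SurveyData:
    """Simulate a survey: community table, metadata, and coordinates.

    Per sample, presence is drawn from per-taxon prevalences with a
    dominant yeast and (usually) a dominant bacterium; an AAB-containing
    indicator event controls the configured fraction of AAB samples;
    planted pairs overwrite presence with the requested sign at the
    requested strength; abundances come from a Dirichlet over present
    taxa with a floor that keeps every present taxon above the 1%
    detection threshold.
    """
    _validate_planted(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    roster = spec.roster
    names = [t.name for t in roster]
    idx = {n: i for i, n in enumerate(names)}
    n, t = spec.n_samples, len(roster)
    if spec.abundance_floor * t >= 0.9:
        raise ValueError("abundance floor too large for roster size")

    # --- metadata ---------------------------------------------------------
    metadata = {}
    types: dict[str, str] = {}
    for var, levels in spec.categorical_vars.items():
        metadata[var] = rng.choice(levels, size=n)
        types[var] = "categorical"
    for var, (mu, sd) in spec.continuous_vars.items():
        metadata[var] = rng.normal(mu, sd, size=n)
        types[var] = "continuous"
    meta = pd.DataFrame(metadata, index=[f"S{i:04d}" for i in range(n)])

    # --- coordinates ------------------------------------------------------
    lat = rng.uniform(*spec.lat_range, size=n)
    lon = rng.uniform(*spec.lon_range, size=n)
    coords = GeoCoordinates(list(meta.index), lat, lon)

    # --- presence probabilities ------------------------------------------
    base = np.tile([t_.prevalence for t_ in roster], (n, 1))

    # spatially smooth per-taxon fields induce distance decay when requested
    if spec.geography == "decay" and spec.decay_rate > 0:
        lat_z = (lat - lat.mean()) / max(lat.std(), 1e-9)
        lon_z = (lon - lon.mean()) / max(lon.std(), 1e-9)
        for j in range(t):
            u, v = rng.normal(size=2)
            field_j = spec.decay_rate * (u * lat_z + v * lon_z)
            base[:, j] = np.clip(base[:, j] + field_j, 0.02, 0.98)
    elif spec.geography not in ("unstructured", "decay"):
        raise ValueError(f"unknown geography model {spec.geography!r}")

    # indicator effects shift presence probability
    alpha_mult = np.ones((n, t))
    for eff in spec.indicator_effects:
        j = idx[eff.taxon]
        if eff.level is not None:
            mask = (meta[eff.variable] == eff.level).to_numpy()
            base[mask, j] = np.clip(base[mask, j] + eff.presence_boost, 0.0, 0.99)
            alpha_mult[mask, j] *= eff.abundance_multiplier
        else:
            z = meta[eff.variable].to_numpy(dtype=float)
            z = (z - z.mean()) / max(z.std(), 1e-9)
            base[:, j] = np.clip(base[:, j] + eff.slope * z, 0.01, 0.99)
            alpha_mult[:, j] *= np.exp(np.log(max(eff.abundance_multiplier, 1e-9)) * z / 2)

    present = rng.random((n, t)) < base

    # AAB containment is a single per-sample event at the target prevalence
    aab_idx = [i for i, t_ in enumerate(roster) if t_.group == "AAB"]
    if aab_idx:
        present[:, aab_idx] = False
        has_aab = rng.random(n) < spec.aab_prevalence
        weights = np.array([roster[i].prevalence for i in aab_idx], dtype=float)
        weights = weights / weights.sum()
        for i in np.flatnonzero(has_aab):
            present[i, rng.choice(aab_idx, p=weights)] = True

    # dominant yeast per sample (always present)
    yeast_idx = [i for i, t_ in enumerate(roster) if t_.group == "yeast"]
    dom_w = np.array([roster[i].dominance_weight for i in yeast_idx], dtype=float)
    dom_yeast = rng.choice(yeast_idx, size=n, p=dom_w / dom_w.sum())
    present[np.arange(n), dom_yeast] = True
    lab_idx = [i for i, t_ in enumerate(roster) if t_.group == "LAB"]
    dom_lab_w = np.array([roster[i].dominance_weight + 0.01 for i in lab_idx])
    dom_lab = rng.choice(lab_idx, size=n, p=dom_lab_w / dom_lab_w.sum())
    present[np.arange(n), dom_lab] = True

    # planted pair constraints
    for p in spec.planted_pairs:
        ja, jb = idx[p.taxon_a], idx[p.taxon_b]
        apply = rng.random(n) < p.strength
        if p.sign == "positive":
            either = present[:, ja] | present[:, jb]
            force = apply & either
            present[force, ja] = True
            present[force, jb] = True
        else:
            both = present[:, ja] & present[:, jb]
            force = apply & both
            drop_a = rng.random(n) < 0.5
            present[force & drop_a, ja] = False
            present[force & ~drop_a, jb] = False

    # --- abundances -------------------------------------------------------
    values = np.zeros((n, t))
    floor = spec.abundance_floor
    for i in range(n):
        s = np.flatnonzero(present[i])
        if s.size == 0:
            s = np.array([dom_yeast[i]])
            present[i, s] = True
        alpha = np.full(s.size, spec.dirichlet_conc) * alpha_mult[i, s]
        alpha[np.isin(s, [dom_yeast[i], dom_lab[i]])] *= spec.dominance_alpha
        w = rng.dirichlet(alpha)
        values[i, s] = floor + (1 - floor * s.size) * w

    data = pd.DataFrame(values, index=meta.index, columns=names)
    annotations = pd.DataFrame(
        {"kingdom": [t_.kingdom for t_ in roster], "group": [t_.group for t_ in roster]},
        index=names,
    )
    table = CommunityTable(data, annotations, relative=True)
    return SurveyData(table, meta, types, coords)


# --------------------------------------------------------------------------
# competitions
# --------------------------------------------------------------------------


def example_competition_design() -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """An 8-species factorial design with study-like outcome structure.

    Returns ``(kingdoms, winners, signs)``: four yeasts and four LAB
    (28 pairs: 16 cross-kingdom, 12 within-kingdom), outcomes with 8/16
    cross-kingdom and 3/12 within-kingdom co-persistences, and eight
    significant co-occurrence signs (four positive, four negative) of
    which exactly seven match the outcomes.
    """
    yeasts = ["S_cerevisiae", "W_anomalus", "K_humilis", "K_servazzii"]
    lab = ["L_sanfranciscensis", "L_brevis", "L_paralimentarius", "L_plantarum"]
    kingdoms = {s: "fungi" for s in yeasts} | {s: "bacteria" for s in lab}

    design = pairwise_design(kingdoms)
    winners: dict[str, str] = {}
    cross = design[design["cross_kingdom"]].reset_index(drop=True)
    within = design[~design["cross_kingdom"]].reset_index(drop=True)
    for i, row in cross.iterrows():
        winners[row["pair"]] = CO_PERSISTENCE if i < 8 else EXCLUSION_B
    for i, row in within.iterrows():
        winners[row["pair"]] = CO_PERSISTENCE if i < 3 else EXCLUSION_B

    co_pairs = [p for p, o in winners.items() if o == CO_PERSISTENCE]
    ex_pairs = [p for p, o in winners.items() if o != CO_PERSISTENCE]
    signs: dict[str, str] = {}
    for p in co_pairs[:3]:
        signs[p] = "positive"  # 3 matches
    signs[ex_pairs[0]] = "positive"  # the single mismatch
    for p in ex_pairs[1:5]:
        signs[p] = "negative"  # 4 matches
    return kingdoms, winners, signs


def generate_competitions(
    winners: dict[str, str],
    kingdoms: dict[str, str],
    n_replicates: int = 5,
    dispersion: float | None = None,
    seed: int = 0,
    transfers: tuple[int, ...] = (1, 3, 6),
    total_cfu: float = 1_000_000.0,
    co_fractions: tuple[float, float] = (0.6, 0.4),
    loser_fraction: float = 0.004,
    limit: float = 0.01,
) -> CompetitionDataset:
    """CFU records realizing prescribed transfer-6 outcomes.

    ``winners`` maps every pair id from :func:`pairwise_design` to an
    outcome class. Target fractions at the focal transfer are
    ``co_fractions`` for co-persistence and ``(1 - loser_fraction,
    loser_fraction)`` for exclusions; earlier transfers interpolate from
    an even split. ``dispersion`` is the negative-binomial size
    parameter (None = noiseless, ``inf`` = Poisson).
    """
    design = pairwise_design(kingdoms)
    missing = set(design["pair"]) - set(winners)
    if missing:
        raise ValueError(f"outcome map missing pairs: {sorted(missing)}")
    if not all(f > limit for f in co_fractions):
        raise ValueError("co-persistence target fractions must exceed the detection limit")
    if loser_fraction > limit:
        raise ValueError("exclusion loser fraction must sit below the detection limit")

    rng = np.random.default_rng(seed)
    final = max(transfers)
    rows = []
    for _, row in design.iterrows():
        pair, a, b = row["pair"], row["species_a"], row["species_b"]
        outcome = winners[pair]
        if outcome == CO_PERSISTENCE:
            target_a = co_fractions[0]
        elif outcome == EXCLUSION_A:
            target_a = loser_fraction
        elif outcome == EXCLUSION_B:
            target_a = 1 - loser_fraction
        else:
            raise ValueError(f"unsupported prescribed outcome {outcome!r} for {pair}")
        for transfer in transfers:
            frac_a = 0.5 + (target_a - 0.5) * transfer / final
            for rep in range(1, n_replicates + 1):
                for species, frac in ((a, frac_a), (b, 1 - frac_a)):
                    mu = total_cfu * frac
                    if dispersion is None:
                        cfu = mu
                    elif np.isinf(dispersion):
                        cfu = rng.poisson(mu)
                    else:
                        p = dispersion / (dispersion + mu)
                        cfu = rng.negative_binomial(dispersion, p)
                    rows.append(
                        {
                            "pair": pair, "species_a": a, "species_b": b,
                            "replicate": rep, "transfer": transfer,
                            "species": species, "cfu": float(cfu),
                        }
                    )
    return CompetitionDataset(pd.DataFrame(rows), dict(kingdoms))


# --------------------------------------------------------------------------
# functional assays
# --------------------------------------------------------------------------


@dataclass
class FunctionSpec:
    n_starters: int = 40
    replicates: int = 3
    rise_intercept: float = 1.3  # mm/hr at 0% AAB
    rise_slope: float = -2.0  # mm/hr per unit AAB fraction (negative)
    rise_noise_sd: float = 0.08
    k_mm: float = 20.0
    n0_mm: float = 0.5
    t_max_h: float = 36.0
    dt_h: float = 0.5
    tube_height_px: float = 800.0
    x0_px: float = 100.0
    n_compounds: int = 25
    n_aab_loaded: int = 8
    loading_scale: float = 6.0
    voc_noise_sd: float = 0.15
    n_blank_compounds: int = 5
    n_blanks: int = 3
    vinegar_threshold: float = 0.15
    seed: int = 0


@dataclass
class FunctionData:
    rise_long: pd.DataFrame  # tube, inoculum, replicate, time_h, pixels
    calibration: pd.DataFrame  # tube, x0, th_px, tube_mm
    true_rates: pd.Series  # per-starter mean rise rate (mm/hr)
    voc: VOCTable  # replicate-level samples
    blanks: VOCTable
    sensory: pd.Series  # per-starter dominant note
    replicate_map: pd.Series  # voc sample id -> starter id
    aab_fraction: pd.Series


def generate_function(spec: FunctionSpec, community: CommunityTable,
                      seed: int | None = None) -> FunctionData:
    """Simulate rise curves, VOC profiles, blanks and sensory notes.

    Rise rates follow ``rise_intercept + rise_slope * %AAB`` plus noise
    (negative slope by default); VOC areas load a latent AAB axis; a
    vinegar-like dominant note is assigned to high-%AAB starters.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    starters = list(community.sample_ids[: spec.n_starters])
    if len(starters) < spec.n_starters:
        raise ValueError("community table has fewer samples than n_starters")
    aab = community.group_fraction("AAB").loc[starters]

    # --- dough rise -------------------------------------------------------
    times = np.arange(0.0, spec.t_max_h + 1e-9, spec.dt_h)
    rise_rows = []
    calib_rows = []
    true_rates = {}
    for s in starters:
        base_r = spec.rise_intercept + spec.rise_slope * float(aab[s])
        base_r = max(base_r, 0.05)
        true_rates[s] = base_r
        for rep in range(1, spec.replicates + 1):
            r = max(base_r + rng.normal(0, spec.rise_noise_sd), 0.05)
            heights = logistic_curve(times, spec.k_mm, spec.n0_mm, r)
            heights = heights - heights[0]
            pixels = spec.x0_px + heights / DEFAULT_TUBE_MM * spec.tube_height_px
            tube = f"{s}_rep{rep}"
            calib_rows.append({"tube": tube, "x0": spec.x0_px,
                               "th_px": spec.tube_height_px, "tube_mm": DEFAULT_TUBE_MM})
            for t_, px in zip(times, pixels):
                rise_rows.append({"tube": tube, "inoculum": s, "replicate": rep,
                                  "time_h": t_, "pixels": px})
    rise_long = pd.DataFrame(rise_rows)
    calibration = pd.DataFrame(calib_rows)

    # --- VOCs -------------------------------------------------------------
    compounds = [f"voc_{i:03d}" for i in range(spec.n_compounds)]
    loadings = np.zeros(spec.n_compounds)
    loaded = rng.choice(spec.n_compounds, size=spec.n_aab_loaded, replace=False)
    loadings[loaded] = spec.loading_scale * rng.uniform(0.5, 1.0, size=spec.n_aab_loaded) * (
        np.where(rng.random(spec.n_aab_loaded) < 0.8, 1.0, -1.0)
    )
    base = rng.uniform(0.5, 2.0, size=spec.n_compounds)

    voc_rows, sample_ids, rep_map = [], [], {}
    for s in starters:
        for rep in range(1, spec.replicates + 1):
            noise = rng.normal(0, spec.voc_noise_sd, size=spec.n_compounds)
            area = np.clip(base + loadings * float(aab[s]) + noise, 0.0, None)
            sid = f"{s}:r{rep}"
            sample_ids.append(sid)
            rep_map[sid] = s
            voc_rows.append(area)

    blank_compounds = [f"blankvoc_{i:02d}" for i in range(spec.n_blank_compounds)]
    blank_level = rng.uniform(0.5, 1.5, size=spec.n_blank_compounds)
    voc_data = pd.DataFrame(voc_rows, index=sample_ids, columns=compounds)
    for c, lvl in zip(blank_compounds, blank_level):
        # contaminant signal in samples never exceeds the blank level
        voc_data[c] = np.clip(rng.uniform(0, 1, size=len(sample_ids)) * lvl, 0, lvl)
    blank_data = pd.DataFrame(
        np.clip(rng.uniform(0.8, 1.0, size=(spec.n_blanks, spec.n_blank_compounds)), 0, None)
        * blank_level,
        index=[f"blank{i}" for i in range(spec.n_blanks)],
        columns=blank_compounds,
    )
    blank_data[blank_compounds] = np.maximum(
        blank_data[blank_compounds].to_numpy(),
        voc_data[blank_compounds].max(axis=0).to_numpy()[None, :],
    )

    # --- sensory ----------------------------------------------------------
    other_notes = ["yeasty", "green_apple", "fermented_sour", "bready"]
    notes = {}
    for s in starters:
        if float(aab[s]) > spec.vinegar_threshold:
            notes[s] = "vinegar"
        else:
            notes[s] = str(rng.choice(other_notes))

    return FunctionData(
        rise_long=rise_long,
        calibration=calibration,
        true_rates=pd.Series(true_rates, name="rise_rate_mm_hr"),
        voc=VOCTable(voc_data),
        blanks=VOCTable(blank_data),
        sensory=pd.Series(notes, name="dominant_note"),
        replicate_map=pd.Series(rep_map, name="starter"),
        aab_fraction=aab,
    )
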
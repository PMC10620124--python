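"""Synthetic shotgun-lipidomics datasets with known ground truth.

The generator emulates the statistical shape of a Lipotype-style
species-level delivery: a lipids x samples pmol matrix over ~19 lipid
classes, a healthy control line plus cancer lines with an optional
treatment arm, a handful of biological replicates per condition,
lognormal baseline abundances with multiplicative replicate noise, and
left-censoring below a detection limit (censored cells are *missing*,
never zero).

Cancer and treatment effects are planted multiplicatively as
``2**(+-effect_log2fc_magnitude)`` according to each lipid's assigned
interaction category, so the ground-truth label algebra matches the
downstream classifier exactly:

* ``moderates``          cancer and treatment effects with opposite signs
* ``amplifies``          same signs
* ``no_treatment_effect``  cancer effect only
* ``side_effect``        treatment effect only
* ``unaffected``         no planted effect

An intensity layer (signal/noise/blank grids) can be derived from a
generated table to exercise the acquisition-stage identification filter
with a controllable fraction of sub-threshold cells.

What this generator does *not* emulate: class-dependent abundance scales,
correlated lipids, batch effects, or intensity-dependent censoring — the
detection limit cuts on the true pmol value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nomenclature
from .ingest import ConcentrationTable
from .interaction import CATEGORIES
from .errors import ValidationError

__all__ = [
    "CellLineSpec",
    "SimulationConfig",
    "IntensityParams",
    "SyntheticTruth",
    "generate",
    "generate_intensity_layer",
]

#: default species counts per class, a plausible plasma-membrane panel
DEFAULT_LIPIDS_PER_CLASS: dict[str, int] = {
    "CE": 10,
    "Cer": 20,
    "HexCer": 10,
    "SM": 20,
    "DAG": 15,
    "TAG": 25,
    "CL": 8,
    "PA": 8,
    "PC": 30,
    "PE": 25,
    "PG": 10,
    "PI": 15,
    "PS": 15,
    "PC O-": 10,
    "PE O-": 8,
    "LPA": 5,
    "LPC": 6,
    "LPE": 6,
    "LPG": 4,
    "LPI": 5,
    "LPS": 5,
}


@dataclass(frozen=True)
class CellLineSpec:
    """One cell line of the design: healthy control or cancer, with an
    optional treatment arm (``treatment=None`` means untreated only)."""

    name: str
    is_cancer: bool = True
    treatment: str | None = None


DEFAULT_CELL_LINES = (
    CellLineSpec("THLE2", is_cancer=False, treatment=None),
    CellLineSpec("HUH7", is_cancer=True, treatment="Wnt3a"),
    CellLineSpec("SNU475", is_cancer=True, treatment="Wnt3a"),
    CellLineSpec("Hep3B", is_cancer=True, treatment="Wnt3a"),
)


def _default_mix() -> dict[str, float]:
    return {cat: 0.2 for cat in CATEGORIES}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset; the defaults are the study design.

    ``base_log10_pmol_mean/sd`` set the lognormal baseline abundance
    (default: median ~32 pmol spanning roughly two orders of magnitude),
    ``replicate_cv`` the multiplicative replicate noise, and
    ``detection_limit_pmol`` the left-censoring threshold (default 3 pmol,
    which censors roughly a tenth of baseline cells).  ``interaction_mix``
    assigns each (lipid, cancer line) pair a ground-truth category; planted
    effects have magnitude ``effect_log2fc_magnitude`` on the log2 scale
    with random signs.  ``class_coherent_effects`` draws one category and
    sign pair per (lipid class, cell line) instead of per lipid, emulating
    class-level regulation trends.
    """

    n_lipids_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LIPIDS_PER_CLASS)
    )
    cell_lines: tuple[CellLineSpec, ...] = DEFAULT_CELL_LINES
    n_replicates: int = 3
    base_log10_pmol_mean: float = 1.5
    base_log10_pmol_sd: float = 0.8
    replicate_cv: float = 0.10
    detection_limit_pmol: float = 3.0
    interaction_mix: dict[str, float] = field(default_factory=_default_mix)
    effect_log2fc_magnitude: float = 2.0
    class_coherent_effects: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_lipids_per_class.values()):
            raise ValidationError("lipid counts must be >= 0")
        if sum(self.n_lipids_per_class.values()) == 0:
            raise ValidationError("config yields 0 lipids")
        unknown = set(self.n_lipids_per_class) - set(nomenclature.CLASS_TABLE)
        if unknown:
            raise ValidationError(f"unknown lipid classes in config: {sorted(unknown)}")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.replicate_cv < 0:
            raise ValidationError("replicate_cv must be >= 0")
        if self.detection_limit_pmol < 0:
            raise ValidationError("detection_limit_pmol must be >= 0")
        if self.effect_log2fc_magnitude <= 0:
            raise ValidationError("effect_log2fc_magnitude must be > 0")
        bad = set(self.interaction_mix) - set(CATEGORIES)
        if bad:
            raise ValidationError(f"unknown interaction categories: {sorted(bad)}")
        total = sum(self.interaction_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"interaction_mix fractions sum to {total}, not 1")
        if not any(line.is_cancer is False for line in self.cell_lines):
            raise ValidationError("design needs a healthy control line")

    @property
    def healthy_line(self) -> CellLineSpec:
        return next(l for l in self.cell_lines if not l.is_cancer)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        if "cell_lines" in raw:
            raw["cell_lines"] = tuple(
                CellLineSpec(**line) if isinstance(line, dict) else line
                for line in raw["cell_lines"]
            )
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated dataset.

    ``effects`` has one row per (lipid, cancer cell line) with the planted
    cancer/treatment log2 fold changes and the interaction category;
    ``censored`` is a lipids x samples boolean grid flagging cells removed
    by the detection limit.
    """

    effects: pd.DataFrame
    censored: pd.DataFrame


_CHAIN_CARBONS = np.arange(12, 25)
_SPHINGO_CLASSES = {"Cer", "HexCer", "SM"}


def _random_species(rng: np.random.Generator, lipid_class: str) -> str:
    arity = nomenclature.arity_of(lipid_class)
    chains = []
    for i in range(arity):
        carbons = int(rng.choice(_CHAIN_CARBONS))
        dbonds = int(rng.integers(0, min(6, carbons // 3) + 1))
        hydroxy = 0
        if lipid_class in _SPHINGO_CLASSES and i == 0:
            carbons, dbonds, hydroxy = 18, 1, int(rng.integers(1, 3))
        chains.append(
            f"{carbons}:{dbonds}" + (f";{hydroxy}" if hydroxy else "")
        )
    return f"{lipid_class} {'/'.join(chains)}"


def _generate_names(rng: np.random.Generator, counts: dict[str, int]) -> list[str]:
    names: list[str] = []
    for lipid_class in sorted(counts):
        chosen: set[str] = set()
        attempts = 0
        while len(chosen) < counts[lipid_class]:
            name = _random_species(rng, lipid_class)
            attempts += 1
            if attempts > 100 * counts[lipid_class] + 1000:
                raise ValidationError(
                    f"cannot draw {counts[lipid_class]} unique {lipid_class} species"
                )
            chosen.add(name)
        names.extend(sorted(chosen))
    return names


_SIGNS = {
    # (cancer sign multiplier, treatment sign rule)
    "moderates": (True, "opposite"),
    "amplifies": (True, "same"),
    "no_treatment_effect": (True, "zero"),
    "side_effect": (False, "free"),
    "unaffected": (False, "zero"),
}


def _draw_effect(
    rng: np.random.Generator, category: str, magnitude: float
) -> tuple[float, float]:
    has_cancer, rule = _SIGNS[category]
    cancer_sign = int(rng.choice([-1, 1])) if has_cancer else 0
    if rule == "opposite":
        treat_sign = -cancer_sign
    elif rule == "same":
        treat_sign = cancer_sign
    elif rule == "free":
        treat_sign = int(rng.choice([-1, 1]))
    else:
        treat_sign = 0
    return cancer_sign * magnitude, treat_sign * magnitude


def _arm_deltas(category: str, sign: int, b: float, m: float) -> tuple[float, float]:
    """Change this lipid causes to the (untreated, treated) arm totals."""
    up, down = b * (2.0**m - 1.0), b * (2.0**-m - 1.0)
    eff = up if sign > 0 else down
    eff2 = b * (2.0 ** (2 * sign * m) - 1.0)
    return {
        "moderates": (eff, 0.0),            # treated multiplier 2^(c-c) = 1
        "amplifies": (eff, eff2),           # treated multiplier 2^(2c)
        "no_treatment_effect": (eff, eff),  # treated multiplier 2^c
        "side_effect": (0.0, eff),          # untreated untouched
    }[category]


def _plant_balanced_effects(
    baseline: np.ndarray, categories: np.ndarray, magnitude: float
) -> tuple[np.ndarray, np.ndarray]:
    """Assign total-conserving cancer/treatment log2 effects for one line.

    mol% is compositional: if planted effects changed a condition's summed
    concentration, every unaffected lipid's mol% would shift and the truth
    labels would be unrecoverable.  Signs are therefore chosen greedily
    (largest baseline first) to keep both arm totals near the baseline
    total, and one balancer species per arm — a ``moderates`` lipid's
    cancer effect (treated-arm neutral) and a treatment-affected lipid's
    treatment effect — absorbs the residual exactly, keeping its direction
    and approximately the nominal magnitude.
    """
    n = baseline.shape[0]
    c_lfc = np.zeros(n)
    t_lfc = np.zeros(n)
    r_untreated = 0.0
    r_treated = 0.0
    affected = [i for i in np.argsort(-baseline) if categories[i] != "unaffected"]
    for i in affected:
        cat, b = categories[i], baseline[i]
        best_sign, best_score = 1, np.inf
        for sign in (1, -1):
            du, dt = _arm_deltas(cat, sign, b, magnitude)
            score = (r_untreated + du) ** 2 + (r_treated + dt) ** 2
            if score < best_score:
                best_sign, best_score = sign, score
        du, dt = _arm_deltas(cat, best_sign, b, magnitude)
        r_untreated += du
        r_treated += dt
        if cat != "side_effect":
            c_lfc[i] = best_sign * magnitude
        if cat == "moderates":
            t_lfc[i] = -best_sign * magnitude
        elif cat == "amplifies":
            t_lfc[i] = best_sign * magnitude
        elif cat == "side_effect":
            t_lfc[i] = best_sign * magnitude

    def absorb(r: float, candidates: list[int], get_mult, apply) -> float:
        """Spread a residual over candidates; each keeps >= 10% of its
        multiplier, so several may be needed when the residual is large
        relative to any single species."""
        for k in sorted(candidates, key=lambda i: -baseline[i] * get_mult(i)):
            if r == 0.0:
                break
            mult = get_mult(k)
            new_mult = mult - r / baseline[k]
            if new_mult < 0.1 * mult:  # partial absorption, move on
                new_mult = 0.1 * mult
            apply(k, new_mult)
            r -= baseline[k] * (mult - new_mult)
        return r

    # balancer pass 1: untreated arm, preferring moderates lipids whose
    # cancer tweak is treated-arm neutral (t stays tied to -c)
    moderates = [i for i in affected if categories[i] == "moderates"]
    other_c = [
        i for i in affected if categories[i] in ("no_treatment_effect", "amplifies")
    ]

    def apply_c(k: int, new_mult: float) -> None:
        nonlocal r_treated
        old_c = c_lfc[k]
        c_lfc[k] = np.log2(new_mult)
        if categories[k] == "moderates":
            t_lfc[k] = -c_lfc[k]
        else:  # treated arm feels the same tweak, scaled by its t effect
            r_treated += baseline[k] * (new_mult - 2.0**old_c) * 2.0 ** t_lfc[k]

    r_untreated = absorb(r_untreated, moderates, lambda i: 2.0 ** c_lfc[i], apply_c)
    r_untreated = absorb(r_untreated, other_c, lambda i: 2.0 ** c_lfc[i], apply_c)

    # balancer pass 2: treated arm via t effects only (untreated untouched)
    t_affected = [i for i in affected if t_lfc[i] != 0.0]

    def apply_t(k: int, new_mult: float) -> None:
        t_lfc[k] = np.log2(new_mult) - c_lfc[k]

    absorb(r_treated, t_affected, lambda i: 2.0 ** (c_lfc[i] + t_lfc[i]), apply_t)
    return c_lfc, t_lfc


def generate(config: SimulationConfig) -> tuple[ConcentrationTable, SyntheticTruth]:
    """Generate a pmol concentration table and its planted truth.

    Fully reproducible from ``config.seed``: the design (names, baselines,
    planted effects) uses one stream and each lipid's replicate noise a
    per-lipid child stream, so truth labels do not depend on noise draws.
    """
    root = np.random.SeedSequence(config.seed)
    design_seq, noise_seq = root.spawn(2)
    rng = np.random.default_rng(design_seq)

    names = _generate_names(rng, config.n_lipids_per_class)
    species = [nomenclature.parse_species(n) for n in names]
    canonical = [nomenclature.canonical_name(s) for s in species]
    n_lipids = len(names)

    # sample sheet
    rows = []
    for line in config.cell_lines:
        arms = [("none", True)]
        if line.treatment is not None:
            arms.append((line.treatment, True))
        for treatment, _ in arms:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{line.name}_{treatment}_r{rep}",
                        "cell_line": line.name,
                        "treatment": treatment,
                        "replicate": rep,
                    }
                )
    samples = pd.DataFrame(rows).set_index("sample_id")

    baseline = 10.0 ** rng.normal(
        config.base_log10_pmol_mean, config.base_log10_pmol_sd, size=n_lipids
    )

    # planted effects per (lipid, cancer line)
    cats = list(CATEGORIES)
    probs = np.array([config.interaction_mix.get(c, 0.0) for c in cats])
    cancer_lines = [l for l in config.cell_lines if l.is_cancer]
    cancer_lfc = {l.name: np.zeros(n_lipids) for l in cancer_lines}
    treat_lfc = {l.name: np.zeros(n_lipids) for l in cancer_lines}
    effect_rows = []
    for line in cancer_lines:
        if config.class_coherent_effects:
            # one (category, signs) draw per class; class trends override
            # total conservation, so labels recover only approximately
            per_class = {
                cls: _draw_effect(
                    rng, rng.choice(cats, p=probs), config.effect_log2fc_magnitude
                )
                for cls in sorted(config.n_lipids_per_class)
            }
            c_arr = np.array([per_class[sp.lipid_class][0] for sp in species])
            t_arr = np.array([per_class[sp.lipid_class][1] for sp in species])
        else:
            categories = np.array([str(c) for c in rng.choice(cats, p=probs, size=n_lipids)])
            c_arr, t_arr = _plant_balanced_effects(
                baseline, categories, config.effect_log2fc_magnitude
            )
        if line.treatment is None:
            # no treatment arm: treatment effects cannot be expressed
            t_arr = np.zeros(n_lipids)
        cancer_lfc[line.name] = c_arr
        treat_lfc[line.name] = t_arr
        for i in range(n_lipids):
            effect_rows.append(
                {
                    "lipid": canonical[i],
                    "cell_line": line.name,
                    "treatment": line.treatment or "none",
                    "cancer_log2fc": c_arr[i],
                    "treatment_log2fc": t_arr[i],
                    "category": _category_from_signs(c_arr[i], t_arr[i]),
                }
            )
    effects = pd.DataFrame(
        effect_rows,
        columns=[
            "lipid",
            "cell_line",
            "treatment",
            "cancer_log2fc",
            "treatment_log2fc",
            "category",
        ],
    )

    # Expected (noise-free) values per cell; planting conserves each arm's
    # total (see _plant_balanced_effects), so mol% fold changes equal the
    # planted log2 effects.
    expected = np.tile(baseline[:, None], (1, len(samples)))
    line_of = samples["cell_line"].to_numpy()
    treat_of = samples["treatment"].to_numpy()
    for j in range(len(samples)):
        name = line_of[j]
        if name in cancer_lfc:
            expected[:, j] *= 2.0 ** cancer_lfc[name]
            if treat_of[j] != "none":
                expected[:, j] *= 2.0 ** treat_lfc[name]

    # multiplicative replicate noise, mean-one lognormal, per-lipid streams
    values = expected.copy()
    if config.replicate_cv > 0:
        sigma = np.sqrt(np.log1p(config.replicate_cv**2))
        for i, child in enumerate(noise_seq.spawn(n_lipids)):
            lrng = np.random.default_rng(child)
            noise = np.exp(lrng.normal(-0.5 * sigma**2, sigma, size=len(samples)))
            values[i] *= noise

    censored_arr = values < config.detection_limit_pmol
    values = np.where(censored_arr, np.nan, values)

    index = pd.Index(canonical, name="lipid")
    table = ConcentrationTable(
        values=pd.DataFrame(values, index=index, columns=samples.index),
        lipids=species,
        samples=samples,
        unit="pmol",
    )
    truth = SyntheticTruth(
        effects=effects,
        censored=pd.DataFrame(censored_arr, index=index, columns=samples.index),
    )
    return table, truth


def _category_from_signs(cancer_log2fc: float, treatment_log2fc: float) -> str:
    if cancer_log2fc and treatment_log2fc:
        same = (cancer_log2fc > 0) == (treatment_log2fc > 0)
        return "amplifies" if same else "moderates"
    if cancer_log2fc:
        return "no_treatment_effect"
    if treatment_log2fc:
        return "side_effect"
    return "unaffected"


@dataclass
class IntensityParams:
    """Controls of the synthetic intensity layer.

    ``snr`` is the signal-to-noise ratio of ordinary cells and
    ``snr_subthreshold`` that of a randomly chosen ``subthreshold_fraction``
    of cells (meant to fall below the filter's cutoff).  ``blank_fraction``
    sets each lipid's blank intensity as a fraction of its median signal.
    """

    gain: float = 1000.0
    snr: float = 10.0
    snr_subthreshold: float = 2.0
    subthreshold_fraction: float = 0.0
    blank_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.subthreshold_fraction <= 1:
            raise ValidationError("subthreshold_fraction must be in [0, 1]")
        if self.snr <= 0 or self.snr_subthreshold <= 0 or self.gain <= 0:
            raise ValidationError("gain and SNR values must be > 0")
        if self.blank_fraction < 0:
            raise ValidationError("blank_fraction must be >= 0")


def generate_intensity_layer(
    table: ConcentrationTable, params: IntensityParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Derive (signal, noise, blank) grids from a concentration table.

    Signal is proportional to pmol (missing cells get signal 0, so the
    filter drops them); noise is signal/SNR with the configured fraction
    of cells forced to the sub-threshold SNR; blank is per lipid.
    """
    params = params or IntensityParams()
    rng = np.random.default_rng(params.seed)
    pmol = table.values.to_numpy(dtype=float)
    signal = np.where(np.isnan(pmol), 0.0, pmol) * params.gain

    snr_grid = np.full(signal.shape, params.snr)
    if params.subthreshold_fraction > 0:
        low = rng.random(signal.shape) < params.subthreshold_fraction
        snr_grid[low] = params.snr_subthreshold
    noise = np.where(signal > 0, signal / snr_grid, 1.0)

    with np.errstate(invalid="ignore"):
        median_signal = np.nanmedian(np.where(signal > 0, signal, np.nan), axis=1)
    median_signal = np.where(np.isnan(median_signal), 0.0, median_signal)
    blank = pd.Series(
        median_signal * params.blank_fraction, index=table.values.index, name="blank"
    )
    idx, cols = table.values.index, table.values.columns
    return (
        pd.DataFrame(signal, index=idx, columns=cols),
        pd.DataFrame(noise, index=idx, columns=cols),
        blank,
    )
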
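"""Synthetic trial cohort generator.

Emulates the data structure of a small neoadjuvant anti-angiogenic trial in
renal cell carcinoma with venous tumour thrombus (VTT): ~20 patients, of
whom ~7 respond (>30% VTT shrinkage by week 9), each described by ~62
baseline blood/tissue/clinical features plus longitudinal plasma angiogenic
markers whose week-3 fold changes become "dynamic" features. A handful of
features genuinely separate responders from non-responders — higher baseline
microvessel density, lower circulating CCL17 and IL-12p70, and a strong
(~7-fold) placental growth factor induction at week 3 in responders — while
the rest are noise. The generator also emits negative-binomial gene counts
with planted differentially expressed genes and exponential progression-free
survival with a configurable hazard ratio, so the transcriptomic-signature
and survival stages can be exercised end to end.

All randomness flows from a single seed through named ``numpy``
``SeedSequence`` substreams, one per data block, so regenerating one block
never perturbs another and a fixed seed yields bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureTable
from .exceptions import ConfigurationError
from .response import classify_cohort

# --------------------------------------------------------------------------
# Default study conditions
# --------------------------------------------------------------------------

#: Baseline feature panel: (marker, source). 62 features across digital
#: pathology of the biopsy, plasma cytokine/angiogenesis panels, peripheral
#: blood flow cytometry and routine clinical variables.
BASELINE_PANEL: list[tuple[str, str]] = [
    # -- tissue (baseline biopsy, digital pathology) --
    ("CD31/CD34 MVD", "tissue"),
    ("CD31 MVD", "tissue"),
    ("CD34 MVD", "tissue"),
    ("SMA area fraction", "tissue"),
    ("CA9 area fraction", "tissue"),
    ("Ki67 index", "tissue"),
    ("CD8 density (tissue)", "tissue"),
    ("CD8/PD-1 density (tissue)", "tissue"),
    ("CD4 density (tissue)", "tissue"),
    ("CD4/FoxP3 density (tissue)", "tissue"),
    ("CD68 density (tissue)", "tissue"),
    # -- plasma cytokine / angiogenesis panels (week 1 levels) --
    ("VEGF-A", "blood"), ("VEGF-C", "blood"), ("VEGF-D", "blood"),
    ("PlGF", "blood"), ("sVEGFR1", "blood"), ("sTie-2", "blood"),
    ("bFGF", "blood"), ("IL-12p70", "blood"), ("IL-7", "blood"),
    ("IL-6", "blood"), ("IL-8", "blood"), ("IL-10", "blood"),
    ("IL-2", "blood"), ("IL-1b", "blood"), ("IL-13", "blood"),
    ("IL-4", "blood"), ("TNF-a", "blood"), ("IFN-g", "blood"),
    ("CCL17", "blood"), ("CCL2", "blood"), ("CCL3", "blood"),
    ("CCL4", "blood"), ("CCL11", "blood"), ("CCL13", "blood"),
    ("CCL22", "blood"), ("CCL26", "blood"), ("CXCL10", "blood"),
    # -- peripheral blood flow cytometry (% of parent) --
    ("CD3 %", "blood"), ("CD4 %", "blood"), ("CD8 %", "blood"),
    ("CD4/CD8 ratio", "blood"), ("Treg %", "blood"),
    ("CD8 PD-1+ %", "blood"), ("CD8 effector %", "blood"),
    ("CD8 naive %", "blood"), ("CD4 effector %", "blood"),
    ("CD4 naive %", "blood"), ("NK %", "blood"), ("NKT %", "blood"),
    ("B cell %", "blood"), ("pDC %", "blood"),
    ("classical monocyte %", "blood"),
    ("intermediate monocyte %", "blood"),
    ("non-classical monocyte %", "blood"),
    ("CD56bright NK %", "blood"), ("CD56dim NK %", "blood"),
    ("naive B %", "blood"), ("memory B %", "blood"),
    ("plasmablast %", "blood"),
    # -- clinical --
    ("age", "clinical"), ("axitinib dose", "clinical"),
    ("baseline VTT length", "clinical"), ("Mayo level", "clinical"),
    ("tumour diameter", "clinical"), ("T stage", "clinical"),
    ("NLR", "clinical"), ("haemoglobin", "clinical"),
    ("platelets", "clinical"), ("eGFR", "clinical"),
]

#: Responder-minus-non-responder location shift, in SD units, for the
#: genuinely discriminative baseline features. Directions follow the
#: univariate trial findings: responders have markedly higher baseline
#: microvessel density, are consistently low in circulating CCL17 and
#: IL-12p70, lower in baseline VEGF-C, and trend lower in circulating
#: CD8+ T cells. Magnitudes are on the scale implied by the reported
#: group comparisons (MVD p~8e-4 at n=12 -> d~2; IL-12p70 p~0.03 at
#: n=19 -> d~1; CCL17 separates the groups almost perfectly in the
#: scaled-density view).
DEFAULT_EFFECT_MAP: dict[str, float] = {
    "CCL17": -2.2,
    "IL-12p70": -1.3,
    "CD31/CD34 MVD": 2.0,
    "CD31 MVD": 1.4,
    "CD34 MVD": 1.4,
    "VEGF-C": -1.0,
    "IL-7": -0.6,
    "CD8 %": -0.5,
}

#: (marker, responder week-3 fold-change multiplier, non-responder
#: multiplier) for the longitudinal plasma angiogenesis panel. PlGF shows a
#: ~7-fold induction in responders at week 3; VEGF-A rises more slowly
#: (significant only late in treatment); sVEGFR1 is modestly higher in
#: responders at week 3; sTie-2 falls slightly but consistently in
#: responders; the remainder are stable.
DEFAULT_PLASMA_MARKERS: list[tuple[str, float, float]] = [
    ("PlGF", 7.0, 1.3),
    ("VEGF-A", 1.4, 1.1),
    ("VEGF-C", 1.0, 1.05),
    ("VEGF-D", 1.0, 1.0),
    ("sVEGFR1", 1.5, 1.1),
    ("sTie-2", 0.65, 0.95),
    ("bFGF", 1.0, 1.0),
]

#: Latent shared factors inducing realistic redundancy among derived flow
#: subsets (these pairs exceed the 0.75 collinearity-pruning threshold) and
#: a weaker shared vessel factor across the three MVD read-outs.
DEFAULT_COLLINEAR_GROUPS: list[tuple[tuple[str, ...], float]] = [
    (("CD3 %", "CD4 %"), 0.85),
    (("CD8 %", "CD8 effector %"), 0.85),
    (("CD31/CD34 MVD", "CD31 MVD", "CD34 MVD"), 0.6),
]

PLASMA_WEEKS = [1, 3, 5, 7, 9]
#: Exponent applied to the log week-3 multiplier at each sampled week:
#: no change at baseline, full effect at week 3, slow decay on treatment,
#: relaxation toward baseline after the drug stops and surgery (week 9).
PLASMA_TIME_PROFILE = {1: 0.0, 3: 1.0, 5: 0.9, 7: 0.75, 9: 0.25}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort. Defaults are the trial conditions."""

    n_patients: int = 20
    n_responders: int = 7
    n_features: int = 62
    effect_map: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MAP))
    missing_rate: float = 0.05
    plasma_markers: list[tuple[str, float, float]] = field(
        default_factory=lambda: list(DEFAULT_PLASMA_MARKERS))
    plasma_log_sd: float = 0.3           # lognormal noise on fold changes
    vtt_shrinkage: tuple[float, float, float] = (-50.0, -10.0, 12.0)
    n_genes: int = 2000
    n_de_genes: int = 40
    de_lfc: float = 3.0
    nb_dispersion: float = 0.2
    surv_hazard_ratio: float = 4.0
    surv_median_months: float = 12.0     # median PFS of the low-hazard group
    censoring_rate: float = 0.02         # hazard (1/month) of indep. censoring
    collinear_groups: list[tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: list(DEFAULT_COLLINEAR_GROUPS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_features <= 0 or self.n_genes <= 0:
            raise ConfigurationError("counts must be > 0")
        if not 0 <= self.n_responders <= self.n_patients:
            raise ConfigurationError("n_responders must be in [0, n_patients]")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ConfigurationError("n_de_genes must be in [0, n_genes]")
        if self.surv_hazard_ratio <= 0:
            raise ConfigurationError("surv_hazard_ratio must be > 0")
        for name, mult_r, mult_nr in self.plasma_markers:
            if mult_r <= 0 or mult_nr <= 0:
                raise ConfigurationError(
                    f"fold-change multipliers must be > 0 (marker {name})")
        if self.n_features < len(BASELINE_PANEL) and self.effect_map:
            panel = {m for m, _ in BASELINE_PANEL[: self.n_features]}
            orphan = set(self.effect_map) - panel
            if orphan:
                raise ConfigurationError(
                    f"effect_map features outside the panel: {sorted(orphan)}")


@dataclass
class SyntheticCohort:
    """One generated cohort; see the block-specific generators for details."""

    spec: CohortSpec
    features: FeatureTable
    labels: pd.DataFrame          # patient_id -> pct_change_w9, responder
    vtt: pd.DataFrame             # long: patient_id, week, rv/ivc segments
    plasma: pd.DataFrame          # long: patient_id, marker, week, value
    expression: pd.DataFrame      # gene x patient counts
    de_truth: dict[str, list[str]]
    survival: pd.DataFrame        # patient_id, time, event

    @property
    def label_vector(self) -> pd.Series:
        return self.labels["responder"].astype(int)

    def write(self, outdir: str | Path) -> None:
        """Write all blocks as plain-text files under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.features.values.to_csv(outdir / "features.csv")
        self.features.meta.to_csv(outdir / "features_meta.csv")
        self.labels.to_csv(outdir / "labels.csv")
        self.vtt.to_csv(outdir / "vtt.csv", index=False)
        self.plasma.to_csv(outdir / "plasma.csv", index=False)
        self.expression.to_csv(outdir / "counts.tsv", sep="\t")
        self.survival.to_csv(outdir / "survival.csv", index=False)
        truth = {
            "de_up": self.de_truth["up"],
            "de_down": self.de_truth["down"],
            "effect_map": self.spec.effect_map,
            "seed": self.spec.seed,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


# --------------------------------------------------------------------------
# Block generators
# --------------------------------------------------------------------------

def _patient_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def _feature_panel(spec: CohortSpec) -> list[tuple[str, str]]:
    panel = list(BASELINE_PANEL)
    if spec.n_features <= len(panel):
        return panel[: spec.n_features]
    extra = [(f"assay feature {i + 1}", "blood")
             for i in range(spec.n_features - len(panel))]
    return panel + extra


def assign_labels(spec: CohortSpec, rng: np.random.Generator) -> pd.Series:
    """Random responder assignment: exactly ``n_responders`` of the cohort."""
    ids = _patient_ids(spec.n_patients)
    resp = np.zeros(spec.n_patients, dtype=bool)
    resp[rng.choice(spec.n_patients, size=spec.n_responders, replace=False)] = True
    return pd.Series(resp, index=pd.Index(ids, name="patient_id"), name="responder")


def generate_features(spec: CohortSpec, labels: pd.Series,
                      rng: np.random.Generator) -> FeatureTable:
    """Latent-Gaussian baseline features with planted group shifts.

    Each feature is unit-variance Gaussian noise; features in a collinear
    group share a latent factor with loading sqrt(rho); features in
    ``effect_map`` gain their configured shift (in SD units) in responders.
    Missing cells are then masked uniformly at random at ``missing_rate``.
    """
    panel = _feature_panel(spec)
    names = [m for m, _ in panel]
    n, p = spec.n_patients, len(panel)
    resp = labels.to_numpy().astype(float)

    x = rng.normal(size=(n, p))
    for group, rho in spec.collinear_groups:
        idx = [names.index(g) for g in group if g in names]
        if len(idx) < 2:
            continue
        factor = rng.normal(size=n)
        load = np.sqrt(rho)
        for j in idx:
            x[:, j] = load * factor + np.sqrt(1 - rho) * x[:, j]
    for feat, shift in spec.effect_map.items():
        if feat in names:
            x[:, names.index(feat)] += shift * resp

    if spec.missing_rate > 0:
        mask = rng.random(size=(n, p)) < spec.missing_rate
        # keep the table imputable: never blank out a full row or column
        for j in np.where(mask.all(axis=0))[0]:
            mask[rng.integers(n), j] = False
        for i in np.where(mask.all(axis=1))[0]:
            mask[i, rng.integers(p)] = False
        x = np.where(mask, np.nan, x)

    values = pd.DataFrame(x, index=pd.Index(labels.index, name="patient_id"),
                          columns=names)
    meta = pd.DataFrame(
        {"marker": names,
         "source": [s for _, s in panel],
         "timepoint": "week1",
         "kind": "level"},
        index=pd.Index(names, name="feature"))
    return FeatureTable(values, meta)


def generate_vtt(spec: CohortSpec, labels: pd.Series,
                 rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """VTT segment lengths at weeks 1, 3 and 9, consistent with the labels.

    Week-9 percent change is drawn from a truncated normal: responders
    strictly below -30%, non-responders at or above it, so the stored label
    always equals the label recomputed from the trajectory. Week 3 shows
    roughly 45% of the final change. Segment lengths shrink proportionally.
    """
    mu_r, mu_nr, sd = spec.vtt_shrinkage
    resp = labels.to_numpy()
    n = spec.n_patients

    pct = np.empty(n)
    eps = 1e-6
    if resp.any():
        a = (-100.0 - mu_r) / sd                   # cannot shrink below -100%
        b = (-30.0 - eps - mu_r) / sd
        pct[resp] = stats.truncnorm.rvs(a, b, loc=mu_r, scale=sd,
                                        size=int(resp.sum()), random_state=rng)
    if (~resp).any():
        a = (-30.0 + eps - mu_nr) / sd
        pct[~resp] = stats.truncnorm.rvs(a, np.inf, loc=mu_nr, scale=sd,
                                         size=int((~resp).sum()), random_state=rng)

    baseline_total = rng.lognormal(mean=np.log(90.0), sigma=0.35, size=n)
    seg_frac = rng.dirichlet([2.0, 3.0, 1.5], size=n)  # rv, ivc above, below
    pct_w3 = np.clip(0.45 * pct + rng.normal(0, 5.0, size=n), -99.0, None)

    rows = []
    for i, pid in enumerate(labels.index):
        for week, scale in ((1, 1.0), (3, 1 + pct_w3[i] / 100), (9, 1 + pct[i] / 100)):
            segs = baseline_total[i] * scale * seg_frac[i]
            rows.append((pid, week, *np.round(segs, 2)))
    vtt = pd.DataFrame(rows, columns=["patient_id", "week", "rv_length",
                                      "ivc_above", "ivc_below"])
    lab = classify_cohort(vtt)
    if not (lab["responder"].reindex(labels.index) == labels).all():
        raise AssertionError("generated VTT trajectories contradict labels")
    return vtt, lab


def generate_plasma_series(spec: CohortSpec, labels: pd.Series,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Longitudinal plasma marker concentrations (pg/mL), weeks 1-9.

    Marker level = patient baseline x multiplier^profile(week) x lognormal
    noise, where the multiplier is the configured geometric-mean week-3 fold
    change for the patient's group and the profile relaxes toward baseline
    by week 9 (treatment stops before surgery).
    """
    resp = labels.to_numpy()
    rows = []
    for marker, mult_r, mult_nr in spec.plasma_markers:
        base = rng.lognormal(mean=np.log(50.0), sigma=0.5, size=spec.n_patients)
        logm = np.where(resp, np.log(mult_r), np.log(mult_nr))
        for week in PLASMA_WEEKS:
            prof = PLASMA_TIME_PROFILE[week]
            noise = (rng.normal(0, spec.plasma_log_sd, size=spec.n_patients)
                     if week != 1 else np.zeros(spec.n_patients))
            vals = base * np.exp(prof * logm + noise)
            rows.extend(zip(labels.index, [marker] * spec.n_patients,
                            [week] * spec.n_patients, np.round(vals, 3)))
    return pd.DataFrame(rows, columns=["patient_id", "marker", "week", "value"])


def generate_expression(spec: CohortSpec, labels: pd.Series,
                        rng: np.random.Generator
                        ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Negative-binomial gene counts with planted DE genes.

    Half the planted genes are up in responders by ``de_lfc`` log2 units in
    expectation, half down; counts are NB with dispersion alpha so that
    var = mu + alpha mu^2.
    """
    genes = [f"G{i + 1:04d}" for i in range(spec.n_genes)]
    resp = labels.to_numpy().astype(float)
    mu0 = rng.lognormal(mean=np.log(50.0), sigma=1.2, size=spec.n_genes)

    n_up = spec.n_de_genes // 2
    de_idx = rng.choice(spec.n_genes, size=spec.n_de_genes, replace=False)
    lfc = np.zeros(spec.n_genes)
    lfc[de_idx[:n_up]] = spec.de_lfc
    lfc[de_idx[n_up:]] = -spec.de_lfc

    mu = mu0[:, None] * np.power(2.0, lfc[:, None] * resp[None, :])
    alpha = spec.nb_dispersion
    if alpha > 0:
        size = 1.0 / alpha
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mu)
    expr = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                        columns=labels.index)
    truth = {"up": [genes[i] for i in de_idx[:n_up]],
             "down": [genes[i] for i in de_idx[n_up:]]}
    return expr, truth


def generate_survival(spec: CohortSpec, group_assignment,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Exponential event times with the configured hazard ratio.

    ``group_assignment`` is a boolean series (True = high-hazard group, e.g.
    non-responder or low-signature stratum). The low-hazard group has median
    ``surv_median_months``; the high-hazard group's event rate is multiplied
    by ``surv_hazard_ratio``. Independent exponential censoring at
    ``censoring_rate`` per month.
    """
    group = pd.Series(group_assignment).astype(bool)
    n = len(group)
    rate_lo = np.log(2) / spec.surv_median_months
    rate = np.where(group.to_numpy(), rate_lo * spec.surv_hazard_ratio, rate_lo)
    t_event = rng.exponential(1.0 / rate)
    if spec.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return pd.DataFrame({
        "patient_id": group.index,
        "time": np.round(time, 4),
        "event": event.astype(int),
        "group": group.to_numpy().astype(int),
    })


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort from one seed; bit-identical for a fixed seed."""
    root = np.random.SeedSequence(spec.seed)
    streams = {name: np.random.default_rng(child) for name, child in
               zip(["labels", "features", "vtt", "plasma", "expression",
                    "survival"], root.spawn(6))}

    resp = assign_labels(spec, streams["labels"])
    features = generate_features(spec, resp, streams["features"])
    vtt, labels = generate_vtt(spec, resp, streams["vtt"])
    labels = labels.reindex(resp.index)
    plasma = generate_plasma_series(spec, resp, streams["plasma"])
    expression, de_truth = generate_expression(spec, resp, streams["expression"])
    # non-responders progress faster: they carry the configured hazard ratio
    survival = generate_survival(spec, ~resp, streams["survival"])
    return SyntheticCohort(spec=spec, features=features, labels=labels,
                           vtt=vtt, plasma=plasma, expression=expression,
                           de_truth=de_truth, survival=survival)
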
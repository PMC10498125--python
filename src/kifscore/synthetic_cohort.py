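"""Synthetic pan-cancer-like cohorts with planted, sign-known structure.

A single latent scalar s ~ N(0,1) per sample drives everything the pipeline
is supposed to detect:

* expression — truth-positive genes load +a*s, truth-negative genes -a*s,
  null genes are pure noise;
* survival — event times are exponential with hazard h0 * exp(beta*s), so a
  Cox screen on a truth gene recovers a hazard ratio of known sign;
  censoring is independent exponential, calibrated numerically to a target
  censored fraction; the three secondary endpoints (DSS/DFI/PFI) re-censor
  the same event process independently;
* copy number — focal / whole-arm / whole-chromosome events at planted
  amplitudes on the toy genome, with carriers sampled preferentially at
  high s (so burden associates positively with the score); background
  segments sit at log2 = 0 and every planted event is recorded;
* mutations — per-sample nonsilent counts are Poisson(rate * exp(gamma*s));
* features — each planted feature attains a target Spearman correlation
  with s via the bivariate-normal identity rho_pearson = 2*sin(pi*rho_s/6).

Everything is deterministic given the spec seed: each table draws from its
own child of a single SeedSequence.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_core import ENDPOINTS, toy_arm_model

__all__ = [
    "CnvEvent",
    "FeaturePlanEntry",
    "CohortSpec",
    "CohortBundle",
    "generate_expression",
    "generate_survival",
    "generate_segments",
    "generate_mutations",
    "generate_features",
    "generate_cohort",
    "generate_selection_panel",
]


@dataclasses.dataclass(frozen=True)
class CnvEvent:
    """One planted event class: carried by ``fraction`` of samples."""

    fraction: float
    kind: str  # focal | arm | chromosome
    amplitude: float


@dataclasses.dataclass(frozen=True)
class FeaturePlanEntry:
    name: str
    spearman: float  # target Spearman correlation with the latent signal


def _default_cnv_plan() -> list[CnvEvent]:
    return [
        CnvEvent(0.3, "focal", 1.2),
        CnvEvent(0.3, "arm", 0.5),
        CnvEvent(0.2, "chromosome", -1.2),
    ]


def _default_feature_plan() -> list[FeaturePlanEntry]:
    return [
        FeaturePlanEntry("chemokine_CXCL16_like", -0.5),
        FeaturePlanEntry("mhc_class_I_like", -0.4),
        FeaturePlanEntry("tfh_infiltration_like", 0.5),
        FeaturePlanEntry("stemness_index_like", 0.4),
    ]


@dataclasses.dataclass
class CohortSpec:
    """Study conditions of a generated cohort.

    Defaults give three cohorts of 500 samples, 10 truth-positive and 10
    truth-negative genes among 60, per-gene loading 1.0 on unit-variance
    noise, a log hazard ratio of 0.8 on the latent signal, 30% censoring.
    """

    n_samples: int = 500  # per cohort
    n_cohorts: int = 3
    n_genes: int = 60
    n_positive: int = 10
    n_negative: int = 10
    loading: float = 1.0  # expression loading a on the latent signal
    noise_sd: float = 1.0
    log_hazard_effect: float = 0.8
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censoring_rate: float = 0.3
    cnv_event_plan: list[CnvEvent] = dataclasses.field(default_factory=_default_cnv_plan)
    cnv_carrier_tilt: float = 0.8  # log-weight on s when sampling event carriers
    focal_length_fraction: float = 0.1  # of the host arm
    mutation_rate: float = 10.0  # mean nonsilent mutations per sample at s = 0
    tmb_log_effect: float = 0.3  # gamma in Poisson(rate * exp(gamma*s))
    feature_plan: list[FeaturePlanEntry] = dataclasses.field(default_factory=_default_feature_plan)
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_positive + self.n_negative > self.n_genes:
            raise ValueError("truth sets exceed the gene universe")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be non-negative")
        for ev in self.cnv_event_plan:
            if not np.isfinite(ev.amplitude):
                raise ValueError("CNV event amplitude must be finite")
            if ev.kind not in ("focal", "arm", "chromosome"):
                raise ValueError(f"unknown CNV event kind {ev.kind!r}")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def positive_truth(self) -> list[str]:
        return self.gene_ids[: self.n_positive]

    @property
    def negative_truth(self) -> list[str]:
        return self.gene_ids[self.n_positive : self.n_positive + self.n_negative]

    @property
    def null_genes(self) -> list[str]:
        return self.gene_ids[self.n_positive + self.n_negative :]


@dataclasses.dataclass
class CohortBundle:
    """The generated cohort plus its ground truth."""

    spec: CohortSpec
    expression: pd.DataFrame  # genes x samples
    clinical: pd.DataFrame
    segments: pd.DataFrame
    mutations: pd.DataFrame
    features: pd.DataFrame  # samples x features
    latent: pd.Series  # the per-sample signal s
    truth_events: pd.DataFrame  # one row per planted CNV event
    arms: pd.DataFrame


def _sample_ids(spec: CohortSpec) -> tuple[list[str], pd.Series]:
    ids, cohorts = [], []
    for c in range(spec.n_cohorts):
        label = f"C{c + 1:02d}"
        for i in range(spec.n_samples):
            ids.append(f"{label}-S{i:04d}")
            cohorts.append(label)
    return ids, pd.Series(cohorts, index=ids, name="cohort")


def generate_expression(
    spec: CohortSpec, rng: np.random.Generator, latent: pd.Series
) -> pd.DataFrame:
    """Log2-scale expression: +-loading * s for truth genes, noise elsewhere."""
    n = len(latent)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    values = noise
    s = latent.to_numpy()
    for i, _ in enumerate(spec.positive_truth):
        values[i] += spec.loading * s
    offset = spec.n_positive
    for i, _ in enumerate(spec.negative_truth):
        values[offset + i] -= spec.loading * s
    return pd.DataFrame(values, index=pd.Index(spec.gene_ids, name="gene"), columns=latent.index)


def _calibrate_censoring(hazards: np.ndarray, target: float) -> float:
    """Rate of an independent exponential censor giving the target censored
    fraction: E[ lc / (lc + h_i) ] = target, solved on a log grid."""
    if target == 0:
        return 0.0

    def censored_fraction(log_lc: float) -> float:
        lc = np.exp(log_lc)
        return float(np.mean(lc / (lc + hazards))) - target

    return float(np.exp(brentq(censored_fraction, -40.0, 40.0)))


def generate_survival(
    latent: pd.Series, spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """All four endpoints plus demographic covariates.

    OS is the primary endpoint; DSS/DFI/PFI share the event process but draw
    independent censoring times, emulating correlated clinical endpoints.
    """
    s = latent.to_numpy()
    n = len(s)
    hazards = spec.baseline_hazard * np.exp(spec.log_hazard_effect * s)
    event_times = rng.exponential(1.0 / hazards)
    lc = _calibrate_censoring(hazards, spec.censoring_rate)

    out = pd.DataFrame({"sample": latent.index})
    for ep in ENDPOINTS:
        if lc > 0:
            censor = rng.exponential(1.0 / lc, size=n)
        else:
            censor = np.full(n, np.inf)
        observed = np.minimum(event_times, censor)
        event = (event_times <= censor).astype(int)
        out[f"{ep}_time"] = np.round(observed, 1)
        out[f"{ep}_event"] = event

    out["age"] = np.round(rng.normal(60, 10, size=n)).clip(25, 95).astype(int)
    out["sex"] = rng.choice(["female", "male"], size=n)
    out["race"] = rng.choice(["groupA", "groupB", "groupC"], size=n, p=[0.6, 0.25, 0.15])
    out["stage_T"] = rng.choice(["T1", "T2", "T3", "T4"], size=n)
    out["stage_N"] = rng.choice(["N0", "N1"], size=n)
    out["stage_M"] = rng.choice(["M0", "M1"], size=n, p=[0.8, 0.2])
    out["vital_status"] = np.where(out["OS_event"] == 1, "dead", "alive")
    return out


def _event_region(kind: str, chrom_idx: int, arms: pd.DataFrame, focal_fraction: float):
    """Deterministic location for the k-th plan entry: each entry owns a
    chromosome (cycled), focal events sit at the start of its p arm."""
    chroms = sorted(arms["chromosome"].unique())
    chrom = chroms[chrom_idx % len(chroms)]
    chrom_arms = arms[arms["chromosome"] == chrom].set_index("arm")
    p, q = chrom_arms.loc["p"], chrom_arms.loc["q"]
    if kind == "chromosome":
        return chrom, None, int(p["start"]), int(q["end"])
    if kind == "arm":
        return chrom, "p", int(p["start"]), int(p["end"])
    length = int((p["end"] - p["start"] + 1) * focal_fraction)
    return chrom, "p", int(p["start"]), int(p["start"]) + length - 1


def generate_segments(
    spec: CohortSpec,
    arms: pd.DataFrame,
    rng: np.random.Generator,
    latent: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segments for every sample plus the planted-event truth record.

    Carriers of each event class are drawn without replacement with weights
    exp(tilt * s), planting a positive burden-score association.  Every arm
    is fully tiled: event pieces at the planted amplitude, the remainder at
    log2 = 0.
    """
    samples = list(latent.index)
    s = latent.to_numpy()
    seg_rows: list[dict] = []
    truth_rows: list[dict] = []

    # per-sample map: arm label -> list of (start, end, amplitude)
    planted: dict[str, list[tuple[str, int, int, float]]] = {sm: [] for sm in samples}
    for k, ev in enumerate(spec.cnv_event_plan):
        n_carriers = int(round(ev.fraction * len(samples)))
        if n_carriers == 0:
            continue
        weights = np.exp(spec.cnv_carrier_tilt * s)
        carriers = rng.choice(samples, size=n_carriers, replace=False, p=weights / weights.sum())
        chrom, arm, start, end = _event_region(ev.kind, k, arms, spec.focal_length_fraction)
        for sm in carriers:
            planted[sm].append((chrom, start, end, ev.amplitude))
            truth_rows.append(
                {"sample": sm, "kind": ev.kind, "chromosome": chrom, "arm": arm,
                 "start": start, "end": end, "amplitude": ev.amplitude}
            )

    arm_recs = list(arms.itertuples(index=False))
    for sm in samples:
        events = planted[sm]
        for a in arm_recs:
            # pieces of this arm covered by events, in coordinate order
            pieces = sorted(
                (max(e_start, a.start), min(e_end, a.end), amp)
                for chrom, e_start, e_end, amp in events
                if chrom == a.chromosome and e_start <= a.end and e_end >= a.start
            )
            cursor = a.start
            for p_start, p_end, amp in pieces:
                if p_start > cursor:
                    seg_rows.append({"sample": sm, "chromosome": a.chromosome,
                                     "start": cursor, "end": p_start - 1, "log2_ratio": 0.0})
                seg_rows.append({"sample": sm, "chromosome": a.chromosome,
                                 "start": p_start, "end": p_end, "log2_ratio": amp})
                cursor = p_end + 1
            if cursor <= a.end:
                seg_rows.append({"sample": sm, "chromosome": a.chromosome,
                                 "start": cursor, "end": a.end, "log2_ratio": 0.0})

    segments = pd.DataFrame(seg_rows, columns=["sample", "chromosome", "start", "end", "log2_ratio"])
    truth = pd.DataFrame(
        truth_rows, columns=["sample", "kind", "chromosome", "arm", "start", "end", "amplitude"]
    )
    return segments, truth


def generate_mutations(
    spec: CohortSpec, rng: np.random.Generator, latent: pd.Series
) -> pd.DataFrame:
    """Nonsilent counts Poisson(rate * exp(gamma*s)), plus ~30% silent calls."""
    rows = []
    genes = spec.gene_ids
    for sm, s in latent.items():
        n_nonsilent = rng.poisson(spec.mutation_rate * np.exp(spec.tmb_log_effect * s))
        n_silent = rng.poisson(0.3 * spec.mutation_rate)
        for _ in range(n_nonsilent):
            rows.append({"sample": sm, "gene": rng.choice(genes),
                         "variant_classification": "Missense_Mutation"})
        for _ in range(n_silent):
            rows.append({"sample": sm, "gene": rng.choice(genes),
                         "variant_classification": "Silent"})
    return pd.DataFrame(rows, columns=["sample", "gene", "variant_classification"])


def generate_features(
    spec: CohortSpec, rng: np.random.Generator, latent: pd.Series
) -> pd.DataFrame:
    """Features with planted Spearman correlation against the latent signal.

    Uses the bivariate-normal link rho_pearson = 2 sin(pi * rho_spearman / 6)
    to hit the target rank correlation in expectation.
    """
    s = latent.to_numpy()
    out = {}
    for entry in spec.feature_plan:
        if not -1 < entry.spearman < 1:
            raise ValueError(f"target Spearman for {entry.name!r} must be in (-1, 1)")
        rho_p = 2.0 * np.sin(np.pi * entry.spearman / 6.0)
        eps = rng.normal(size=len(s))
        out[entry.name] = rho_p * s + np.sqrt(1.0 - rho_p**2) * eps
    return pd.DataFrame(out, index=latent.index.rename("sample"))


def generate_cohort(spec: CohortSpec | None = None) -> CohortBundle:
    """Generate the full bundle; fully deterministic given ``spec.seed``."""
    spec = spec or CohortSpec()
    ss = np.random.SeedSequence(spec.seed)
    keys = ("latent", "expression", "survival", "segments", "mutations", "features")
    rngs = dict(zip(keys, (np.random.default_rng(c) for c in ss.spawn(len(keys)))))

    ids, cohorts = _sample_ids(spec)
    latent = pd.Series(rngs["latent"].normal(size=len(ids)), index=pd.Index(ids, name="sample"), name="latent")

    expression = generate_expression(spec, rngs["expression"], latent)
    clinical = generate_survival(latent, spec, rngs["survival"])
    clinical.insert(1, "cohort", cohorts.to_numpy())
    arms = toy_arm_model()
    segments, truth = generate_segments(spec, arms, rngs["segments"], latent)
    mutations = generate_mutations(spec, rngs["mutations"], latent)
    features = generate_features(spec, rngs["features"], latent)

    return CohortBundle(
        spec=spec, expression=expression, clinical=clinical, segments=segments,
        mutations=mutations, features=features, latent=latent,
        truth_events=truth, arms=arms,
    )


def generate_selection_panel(
    n_samples: int = 300,
    n_informative: int = 4,
    n_noise: int = 4,
    effect: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Small candidate-gene panel for consensus feature selection.

    Informative genes shift by ``effect`` between the two classes; noise
    genes do not.  Returns (X samples x genes, binary labels, informative
    gene names).
    """
    rng = np.random.default_rng(seed)
    n_genes = n_informative + n_noise
    genes = [f"P{i:02d}" for i in range(n_genes)]
    y = rng.integers(0, 2, size=n_samples)
    X = rng.normal(size=(n_samples, n_genes))
    X[:, :n_informative] += effect * y[:, None]
    idx = pd.Index([f"S{i:04d}" for i in range(n_samples)], name="sample")
    return (
        pd.DataFrame(X, index=idx, columns=genes),
        pd.Series(y, index=idx, name="group"),
        genes[:n_informative],
    )
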
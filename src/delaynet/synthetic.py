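"""Synthetic cohorts with known directed lagged structure.

Real resting-state cohorts with PET staging are access-restricted, so the
package ships a generator that emulates their statistical shape: ~166
subjects in four diagnostic groups (amyloid-negative controls, and
amyloid-positive controls, MCI and AD dementia patients; default counts
81/36/31/18), 200 brain regions, directed lagged couplings that produce
group-dependent clustering/efficiency trajectories, and outcome variables
linked quadratically to network measures.

Time series come from a stable vector-autoregressive (VAR) process

    x(t) = sum_l B_l x(t-l) + eps(t),    eps ~ N(0, sd^2 I),

whose lag matrices are assembled from explicit couplings (source region,
target region, lag, strength).  Stability is checked at build time via
the spectral radius of the companion matrix.  Each group's coupling
template is a directed ring backbone (every region drives its next
neighbours at lag 1) with a group-specific fraction of couplings rewired
to random long-range targets — rewiring creates shortcuts, so the global
efficiency of the recovered directed network rises with it.  A weak
self-coupling makes the signals autocorrelated, as haemodynamic signals
are.

Group membership follows the amyloid-PET classification rule used
clinically: a global amyloid SUVR above 1.11 is amyloid-positive; MCI/AD
subjects below the cut-off are excluded from the disease continuum.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .connectivity import TimeSeriesMatrix

logger = logging.getLogger(__name__)

COGNITIVE_TESTS = ("ADAS13", "ADASQ4", "mPACC", "CF", "TrailA", "TrailB")
GROUP_NAMES = ("CN_Abeta_neg", "CN_Abeta_pos", "MCI_Abeta_pos", "AD_Abeta_pos")
ABETA_CUTOFF = 1.11

_METADATA_COLUMNS = [
    "subject_id",
    "diagnosis",
    "group",
    "global_abeta_suvr",
    "braak12_suvr",
    "braak34_suvr",
    "braak56_suvr",
    "age",
    "sex",
    "education",
    "apoe4_copies",
    *COGNITIVE_TESTS,
]

# covariate distributions loosely matched to published cohort medians;
# only realistic variance matters, not exact replication
_AGE_MEAN, _AGE_SD = 76.0, 7.0
_EDU_MEAN, _EDU_SD = 16.0, 3.0
_APOE_PROBS = {  # counts of epsilon-4 copies (0/1/2) per group
    "CN_Abeta_neg": (0.78, 0.21, 0.01),
    "CN_Abeta_pos": (0.53, 0.44, 0.03),
    "MCI_Abeta_pos": (0.45, 0.32, 0.23),
    "AD_Abeta_pos": (0.61, 0.33, 0.06),
}
_BRAAK_MEANS = {  # (I-II, III-IV, V-VI) SUVR centres per group
    "CN_Abeta_neg": (1.1, 1.1, 1.0),
    "CN_Abeta_pos": (1.1, 1.2, 1.0),
    "MCI_Abeta_pos": (1.3, 1.2, 1.1),
    "AD_Abeta_pos": (1.5, 1.4, 1.1),
}
_COG_MEANS = {  # per-test centres per group, ordered as COGNITIVE_TESTS
    "CN_Abeta_neg": (12.0, 2.0, 1.5, 22.0, 30.0, 75.0),
    "CN_Abeta_pos": (13.3, 3.0, -0.4, 22.0, 32.0, 80.0),
    "MCI_Abeta_pos": (19.3, 5.0, -3.9, 16.0, 39.0, 110.0),
    "AD_Abeta_pos": (32.3, 8.0, -14.9, 13.5, 51.5, 160.0),
}
_COG_SDS = (5.0, 1.5, 4.0, 4.0, 10.0, 30.0)


@dataclass(frozen=True)
class CouplingSpec:
    """One directed lagged coupling: source drives target after ``lag`` steps."""

    source: int
    target: int
    lag: int
    strength: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("source and target must differ (self-loops use self_coupling)")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")


@dataclass(frozen=True)
class QuadraticLink:
    """Outcome = intercept + b1*m + b2*m^2 + covariate effects + noise."""

    intercept: float = 0.0
    linear_coef: float = 0.0
    quadratic_coef: float = 0.0
    covariate_coefs: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    """Design of one diagnostic group in a simulated cohort."""

    name: str
    n_subjects: int
    coupling_template: tuple[CouplingSpec, ...]
    noise_sd: float = 1.0
    self_coupling: float = 0.0
    strength_jitter_sd: float = 0.1
    outcome_model: QuadraticLink | None = None

    def __post_init__(self) -> None:
        if self.name not in GROUP_NAMES:
            raise ValueError(f"unknown group name {self.name!r}; use one of {GROUP_NAMES}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        object.__setattr__(self, "coupling_template", tuple(self.coupling_template))


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    diagnosis: str
    global_abeta_suvr: float
    braak12_suvr: float
    braak34_suvr: float
    braak56_suvr: float
    age: float
    sex: str
    education: float
    apoe4_copies: int
    cognitive_scores: Mapping[str, float]
    group: str

    def __post_init__(self) -> None:
        for name in ("global_abeta_suvr", "braak12_suvr", "braak34_suvr", "braak56_suvr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.apoe4_copies not in (0, 1, 2):
            raise ValueError("apoe4_copies must be 0, 1 or 2")
        expected = classify_group(self.diagnosis, self.global_abeta_suvr)
        if expected != self.group:
            raise ValueError(
                f"group {self.group!r} inconsistent with diagnosis/SUVR -> {expected!r}"
            )


@dataclass(frozen=True)
class CohortDataset:
    """Subjects, their time series, and extra outcome columns."""

    subjects: tuple[SubjectRecord, ...]
    timeseries: Mapping[str, TimeSeriesMatrix]
    design_seed: int | None = None
    outcomes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")
        missing = [i for i in ids if i not in self.timeseries]
        if missing:
            raise ValueError(f"missing time series for: {missing}")
        shapes = {self.timeseries[i].data.shape for i in ids}
        regions = {s[0] for s in shapes}
        if len(regions) > 1:
            raise ValueError("all subjects must share the region count")
        object.__setattr__(self, "subjects", tuple(self.subjects))

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "diagnosis": s.diagnosis,
                "group": s.group,
                "global_abeta_suvr": s.global_abeta_suvr,
                "braak12_suvr": s.braak12_suvr,
                "braak34_suvr": s.braak34_suvr,
                "braak56_suvr": s.braak56_suvr,
                "age": s.age,
                "sex": s.sex,
                "education": s.education,
                "apoe4_copies": s.apoe4_copies,
            }
            row.update({t: s.cognitive_scores[t] for t in COGNITIVE_TESTS})
            for name, mapping in self.outcomes.items():
                row[name] = mapping[s.subject_id]
            rows.append(row)
        return pd.DataFrame(rows, columns=_METADATA_COLUMNS + list(self.outcomes))


def lag_matrices(
    n_regions: int, couplings: Iterable[CouplingSpec], self_coupling: float = 0.0
) -> dict[int, np.ndarray]:
    """Assemble VAR lag matrices B_l (target row, source column)."""
    mats: dict[int, np.ndarray] = {}
    for c in couplings:
        if not (0 <= c.source < n_regions and 0 <= c.target < n_regions):
            raise ValueError(f"coupling {c} outside region range 0..{n_regions - 1}")
        mats.setdefault(c.lag, np.zeros((n_regions, n_regions)))
        mats[c.lag][c.target, c.source] += c.strength
    if self_coupling:
        mats.setdefault(1, np.zeros((n_regions, n_regions)))
        mats[1][np.diag_indices(n_regions)] += self_coupling
    return mats


def companion_spectral_radius(mats: Mapping[int, np.ndarray], n_regions: int) -> float:
    """Spectral radius of the VAR companion matrix (stability iff < 1)."""
    if not mats:
        return 0.0
    p = max(mats)
    comp = np.zeros((n_regions * p, n_regions * p))
    for lag in range(1, p + 1):
        if lag in mats:
            comp[:n_regions, (lag - 1) * n_regions : lag * n_regions] = mats[lag]
    if p > 1:
        comp[n_regions:, : n_regions * (p - 1)] = np.eye(n_regions * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def simulate_var_timeseries(
    n_regions: int,
    n_timepoints: int,
    couplings: Iterable[CouplingSpec] = (),
    noise_sd: float = 1.0,
    seed: int = 0,
    *,
    self_coupling: float = 0.0,
    burn_in: int = 200,
    region_labels: Sequence[str] | None = None,
    tr_seconds: float = 3.0,
) -> TimeSeriesMatrix:
    """Draw one subject's regions x timepoints matrix from a stable VAR.

    The process is rejected with a diagnostic naming the spectral radius
    if the coupling set is unstable, and rejected if any lag reaches
    ``n_timepoints``.  Identical inputs and seed reproduce the output
    bit-for-bit.
    """
    couplings = tuple(couplings)
    if couplings:
        max_lag = max(c.lag for c in couplings)
        if max_lag >= n_timepoints:
            raise ValueError(f"lag {max_lag} >= n_timepoints {n_timepoints}")
    mats = lag_matrices(n_regions, couplings, self_coupling)
    radius = companion_spectral_radius(mats, n_regions)
    if radius >= 1.0:
        raise ValueError(
            f"unstable coupling set: companion spectral radius {radius:.4f} >= 1"
        )
    p = max(mats) if mats else 0
    rng = np.random.default_rng(seed)
    total = n_timepoints + burn_in
    x = np.zeros((n_regions, total + p))
    eps = rng.normal(0.0, noise_sd, size=(n_regions, total))
    for t in range(total):
        acc = eps[:, t].copy()
        for lag, B in mats.items():
            acc += B @ x[:, t + p - lag]
        x[:, t + p] = acc
    data = x[:, p + burn_in :]
    if region_labels is None:
        region_labels = [f"R{i:03d}" for i in range(n_regions)]
    return TimeSeriesMatrix(
        region_labels=tuple(region_labels), data=data, tr_seconds=tr_seconds
    )


def classify_group(diagnosis: str, global_abeta_suvr: float) -> str:
    """Assign the diagnostic group from diagnosis and amyloid SUVR.

    Amyloid positivity requires SUVR strictly above 1.11.  MCI/AD without
    amyloid pathology fall outside the disease continuum -> "excluded".
    """
    if global_abeta_suvr <= 0:
        raise ValueError("SUVR must be positive")
    positive = global_abeta_suvr > ABETA_CUTOFF
    if diagnosis == "CN":
        return "CN_Abeta_pos" if positive else "CN_Abeta_neg"
    if diagnosis == "MCI":
        return "MCI_Abeta_pos" if positive else "excluded"
    if diagnosis == "AD":
        return "AD_Abeta_pos" if positive else "excluded"
    raise ValueError(f"unknown diagnosis {diagnosis!r}; expected CN, MCI or AD")


_DIAGNOSIS_OF_GROUP = {
    "CN_Abeta_neg": "CN",
    "CN_Abeta_pos": "CN",
    "MCI_Abeta_pos": "MCI",
    "AD_Abeta_pos": "AD",
}


def _jittered_couplings(
    template: tuple[CouplingSpec, ...], jitter_sd: float, rng: np.random.Generator
) -> tuple[CouplingSpec, ...]:
    if jitter_sd <= 0:
        return template
    factors = rng.normal(1.0, jitter_sd, size=len(template))
    # truncate at +/-3 sd: keeps the jittered process provably stable
    # whenever the design's worst-case row-sum budget is below 1
    factors = np.clip(factors, max(1 - 3 * jitter_sd, 0.1), 1 + 3 * jitter_sd)
    return tuple(
        replace(c, strength=c.strength * f) for c, f in zip(template, factors)
    )


def _draw_subject(
    group: GroupSpec, subject_id: str, rng: np.random.Generator
) -> SubjectRecord:
    diagnosis = _DIAGNOSIS_OF_GROUP[group.name]
    if group.name == "CN_Abeta_neg":
        suvr = rng.uniform(0.9, ABETA_CUTOFF)
    else:
        suvr = rng.uniform(ABETA_CUTOFF + 0.01, 1.6)
    braak = _BRAAK_MEANS[group.name]
    cog = _COG_MEANS[group.name]
    scores = {
        t: float(rng.normal(mu, sd)) for t, mu, sd in zip(COGNITIVE_TESTS, cog, _COG_SDS)
    }
    return SubjectRecord(
        subject_id=subject_id,
        diagnosis=diagnosis,
        global_abeta_suvr=float(suvr),
        braak12_suvr=float(max(rng.normal(braak[0], 0.15), 0.5)),
        braak34_suvr=float(max(rng.normal(braak[1], 0.15), 0.5)),
        braak56_suvr=float(max(rng.normal(braak[2], 0.15), 0.5)),
        age=float(rng.normal(_AGE_MEAN, _AGE_SD)),
        sex="F" if rng.random() < 0.5 else "M",
        education=float(rng.normal(_EDU_MEAN, _EDU_SD)),
        apoe4_copies=int(rng.choice(3, p=_APOE_PROBS[group.name])),
        cognitive_scores=scores,
        group=group.name,
    )


def simulate_cohort(
    design: Sequence[GroupSpec],
    n_regions: int,
    n_timepoints: int,
    seed: int = 0,
    *,
    tr_seconds: float = 3.0,
) -> CohortDataset:
    """Simulate a full cohort: time series, demographics, PET and cognition.

    Each subject's VAR uses the group coupling template with multiplicative
    Gaussian strength jitter, so within-group network metrics have
    nonzero variance.  Deterministic under ``seed``.
    """
    if not design:
        raise ValueError("design must contain at least one group")
    names = [g.name for g in design]
    if len(set(names)) != len(names):
        raise ValueError("group names must be unique within a design")
    root = np.random.SeedSequence(seed)
    subjects: list[SubjectRecord] = []
    timeseries: dict[str, TimeSeriesMatrix] = {}
    counter = 0
    for group in design:
        for _ in range(group.n_subjects):
            counter += 1
            sid = f"sub-{counter:04d}"
            child = root.spawn(1)[0]
            rng = np.random.default_rng(child)
            couplings = _jittered_couplings(
                group.coupling_template, group.strength_jitter_sd, rng
            )
            ts_seed = int(child.generate_state(1)[0] % (2**31))
            ts = simulate_var_timeseries(
                n_regions,
                n_timepoints,
                couplings,
                group.noise_sd,
                ts_seed,
                self_coupling=group.self_coupling,
                tr_seconds=tr_seconds,
            )
            subjects.append(_draw_subject(group, sid, rng))
            timeseries[sid] = ts
    return CohortDataset(subjects=tuple(subjects), timeseries=timeseries, design_seed=seed)


def attach_quadratic_outcome(
    cohort: CohortDataset,
    measure_values: Mapping[str, float],
    link: QuadraticLink,
    outcome_name: str,
    seed: int = 0,
) -> CohortDataset:
    """Store ``intercept + b1*m + b2*m² + covariates + noise`` per subject.

    Covariate effects reference the numeric metadata columns named in
    ``link.covariate_coefs``.  Returns a new cohort with the outcome
    column added.
    """
    missing = [s.subject_id for s in cohort.subjects if s.subject_id not in measure_values]
    if missing:
        raise ValueError(f"missing measure value for subject(s): {missing}")
    rng = np.random.default_rng(seed)
    meta = cohort.metadata_frame().set_index("subject_id")
    values: dict[str, float] = {}
    for s in cohort.subjects:
        m = float(measure_values[s.subject_id])
        y = link.intercept + link.linear_coef * m + link.quadratic_coef * m**2
        for cov, coef in link.covariate_coefs.items():
            y += coef * float(meta.loc[s.subject_id, cov])
        if link.noise_sd > 0:
            y += rng.normal(0.0, link.noise_sd)
        values[s.subject_id] = float(y)
    outcomes = dict(cohort.outcomes)
    outcomes[outcome_name] = values
    return replace(cohort, outcomes=outcomes)


def write_cohort(cohort: CohortDataset, directory: str | Path) -> list[Path]:
    """Write one time-series TSV per subject plus ``subjects.csv``.

    TSV layout: first column ``region`` (labels), remaining columns the
    timepoint indices.  Values are printed at full precision so a
    read-back round-trips bit-identically.  Returns the manifest of
    written paths (time series first, metadata last).
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        probe = directory / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"directory not writable: {directory}") from exc
    manifest: list[Path] = []
    for sid in cohort.subject_ids:
        ts = cohort.timeseries[sid]
        path = directory / f"{sid}_ts.tsv"
        df = pd.DataFrame(
            ts.data,
            index=list(ts.region_labels),
            columns=[str(t) for t in range(ts.n_timepoints)],
        )
        df.to_csv(path, sep="\t", index_label="region", float_format="%.17g")
        manifest.append(path)
    meta_path = directory / "subjects.csv"
    cohort.metadata_frame().to_csv(meta_path, index=False, float_format="%.17g")
    manifest.append(meta_path)
    return manifest


def read_cohort(directory: str | Path, tr_seconds: float = 3.0) -> CohortDataset:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    meta_path = directory / "subjects.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata file: {meta_path}")
    meta = pd.read_csv(meta_path, float_precision="round_trip")
    subjects: list[SubjectRecord] = []
    timeseries: dict[str, TimeSeriesMatrix] = {}
    extra_cols = [c for c in meta.columns if c not in _METADATA_COLUMNS]
    outcomes: dict[str, dict[str, float]] = {c: {} for c in extra_cols}
    for _, row in meta.iterrows():
        sid = str(row["subject_id"])
        ts_path = directory / f"{sid}_ts.tsv"
        if not ts_path.exists():
            raise FileNotFoundError(f"missing time-series file for subject {sid}: {ts_path}")
        df = pd.read_csv(ts_path, sep="\t", index_col=0, float_precision="round_trip")
        timeseries[sid] = TimeSeriesMatrix(
            region_labels=tuple(str(r) for r in df.index),
            data=df.to_numpy(dtype=float),
            tr_seconds=tr_seconds,
        )
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                diagnosis=str(row["diagnosis"]),
                global_abeta_suvr=float(row["global_abeta_suvr"]),
                braak12_suvr=float(row["braak12_suvr"]),
                braak34_suvr=float(row["braak34_suvr"]),
                braak56_suvr=float(row["braak56_suvr"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=float(row["education"]),
                apoe4_copies=int(row["apoe4_copies"]),
                cognitive_scores={t: float(row[t]) for t in COGNITIVE_TESTS},
                group=str(row["group"]),
            )
        )
        for c in extra_cols:
            outcomes[c][sid] = float(row[c])
    return CohortDataset(subjects=tuple(subjects), timeseries=timeseries, outcomes=outcomes)


def ring_lattice_couplings(
    n_regions: int,
    n_neighbors: int = 2,
    rewire_prob: float = 0.0,
    strength: float = 0.3,
    lag: int = 1,
    seed: int = 0,
) -> tuple[CouplingSpec, ...]:
    """Directed ring backbone with random long-range rewiring.

    Every region drives its ``n_neighbors`` clockwise neighbours at the
    given lag; each coupling's target is rewired to a uniform random
    region with probability ``rewire_prob`` (avoiding self-loops and
    duplicate targets).  Low rewiring gives a locally clustered,
    low-efficiency topology; high rewiring adds shortcuts and raises
    global efficiency — the knob the cohort designs use to plant
    group-dependent efficiency trajectories.
    """
    if n_neighbors < 1 or n_neighbors >= n_regions:
        raise ValueError("need 1 <= n_neighbors < n_regions")
    rng = np.random.default_rng(seed)
    couplings: list[CouplingSpec] = []
    targets_of: dict[int, set[int]] = {i: set() for i in range(n_regions)}
    for i in range(n_regions):
        for off in range(1, n_neighbors + 1):
            j = (i + off) % n_regions
            if rewire_prob > 0 and rng.random() < rewire_prob:
                choices = [
                    t for t in range(n_regions) if t != i and t not in targets_of[i]
                ]
                j = int(rng.choice(choices))
            if j in targets_of[i]:
                continue
            targets_of[i].add(j)
            couplings.append(CouplingSpec(source=i, target=j, lag=lag, strength=strength))
    return tuple(couplings)


def load_design_config(path: str | Path | None = None) -> dict:
    """Load a cohort design config (YAML); defaults to the bundled one."""
    if path is None:
        ref = importlib.resources.files("delaynet") / "data" / "default_design.yaml"
        return yaml.safe_load(ref.read_text())
    return yaml.safe_load(Path(path).read_text())


def reduced_design_config(
    n_regions: int = 30,
    n_per_group: Sequence[int] = (10, 10, 10, 10),
    n_timepoints: int = 197,
) -> dict:
    """The bundled design at desk scale: same couplings/noise, fewer
    regions and subjects.  Used by the example analyses and tests."""
    cfg = load_design_config()
    cfg["n_regions"] = int(n_regions)
    cfg["n_timepoints"] = int(n_timepoints)
    for g, n in zip(cfg["groups"], n_per_group):
        g["n_subjects"] = int(n)
    return cfg


def design_from_config(config: dict, seed: int = 0) -> list[GroupSpec]:
    """Build GroupSpecs from a design config.

    The config holds, per group, the backbone parameters (neighbours,
    rewiring probability, strength), noise, self-coupling and jitter;
    the backbone itself is sampled deterministically from ``seed`` so a
    design is a pure function of (config, seed).
    """
    n_regions = int(config["n_regions"])
    groups: list[GroupSpec] = []
    root = np.random.SeedSequence(seed)
    for i, g in enumerate(config["groups"]):
        backbone = g.get("backbone", {})
        template = ring_lattice_couplings(
            n_regions,
            n_neighbors=int(backbone.get("n_neighbors", 2)),
            rewire_prob=float(backbone.get("rewire_prob", 0.0)),
            strength=float(backbone.get("strength", 0.3)),
            lag=int(backbone.get("lag", 1)),
            seed=int(root.spawn(1)[0].generate_state(1)[0] % (2**31)),
        )
        groups.append(
            GroupSpec(
                name=str(g["name"]),
                n_subjects=int(g["n_subjects"]),
                coupling_template=template,
                noise_sd=float(g.get("noise_sd", 1.0)),
                self_coupling=float(g.get("self_coupling", 0.3)),
                strength_jitter_sd=float(g.get("strength_jitter_sd", 0.1)),
            )
        )
    return groups
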
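"""Eta-Mu model for weighted deficit profiling of psychometric test batteries.

Children with learning disabilities are routinely assessed with batteries of
standardized visuoperceptive (VP) and visuomotor-coordination (VMC) tests,
each reported as an age-normed z-score (negative = below norm).  Most tests
recruit both domains, in proportions that can be judged in advance: a spatial
memory span is essentially pure VP, a handwriting test is mostly VMC.  The
Eta-Mu model turns a profile of z-scores into two weighted impairment
indices,

    eta = -sum_n (VP_n * z_n) / n        (VP impairment)
    mu  = -sum_n (VMC_n * z_n) / n       (VMC impairment)

where VP_n + VMC_n = 100 for every test and n is the number of tests
administered.  Both indices are 0 for a normal profile and grow as
performance falls below norms.  A subject equally impaired in both domains
(identical z on every test) would show

    eta_exp = mean(VP) * |avg_z|,   mu_exp = mean(VMC) * |avg_z|,

so the excesses delta_eta = eta - eta_exp and delta_mu = mu - mu_exp
localise the deficit: a positive delta_eta marks a prevalent VP defect, a
positive delta_mu a prevalent VMC defect, and both near zero points at the
VP/VMC *integration* level rather than either domain.  Because the per-test
weights sum to 100, delta_eta = -delta_mu whenever avg_z <= 0.

The module is organised in the order the method runs:

1.  battery     -- test definitions, recruitment weights, subset means
2.  scoring     -- eta/mu, expected baselines, deltas, classification
3.  cohort      -- Tukey-hinge summaries and pre/post comparison
4.  synthetic   -- generative simulator and parameter-recovery experiment
5.  io          -- tidy subject tables, shipped reference data, reports

Sessions may be incomplete (a child refusing a test is common); every
computation then runs over the administered subset and the expected-value
weights are re-averaged over that subset.
"""

from __future__ import annotations

import csv
import io as _io
import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_TOLERANCE",
    "Z_OUTLIER_THRESHOLD",
    "TestDefinition",
    "Battery",
    "default_battery",
    "validate_battery",
    "mean_weights",
    "load_battery",
    "save_battery",
    "SubjectSession",
    "DeficitClass",
    "EtaMuResult",
    "average_z",
    "compute_eta",
    "compute_mu",
    "expected_indices",
    "score_session",
    "model_lines",
    "CohortSummary",
    "SessionComparison",
    "tukey_hinges",
    "cohort_summary",
    "compare_sessions",
    "ImpairmentProfile",
    "simulate_session",
    "simulate_cohort",
    "RecoveryResult",
    "recovery_experiment",
    "read_subject_table",
    "write_subject_table",
    "read_wide_table",
    "load_example_session",
    "load_pilot_cohort",
    "results_frame",
    "build_report",
    "render_markdown",
]

logger = logging.getLogger("etamu")

#: Half-width of the "balanced" band on delta_eta / delta_mu, in the same
#: arbitrary units as eta and mu.  Profiles whose delta values stay within
#: the band are classified BALANCED (boundary inclusive).
DEFAULT_TOLERANCE: float = 2.0

#: |z| beyond which an input value is flagged as implausible (z-scores of
#: age-normed clinical tests essentially never exceed 5 in magnitude).
Z_OUTLIER_THRESHOLD: float = 5.0


# ---------------------------------------------------------------------------
# 1. battery -- tests, recruitment weights, subset means
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestDefinition:
    """One battery test with its assumed VP/VMC recruitment split.

    Weights are integer percents and must sum to 100: they encode the
    judged share of visuoperceptive vs. visuomotor-coordination involvement
    in performing the test.
    """

    __test__ = False  # domain object, not a test case, despite the name

    name: str
    vp_weight: int
    vmc_weight: int


@dataclass(frozen=True)
class Battery:
    """An ordered collection of tests the model scores against."""

    tests: tuple[TestDefinition, ...]
    label: str = "battery"

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.tests)

    def __getitem__(self, name: str) -> TestDefinition:
        for t in self.tests:
            if t.name == name:
                return t
        raise KeyError(f"test {name!r} not in battery {self.label!r}")

    def subset(self, names: Iterable[str]) -> "Battery":
        """Battery restricted to *names*, keeping the original order."""
        keep = set(names)
        unknown = keep - set(self.names)
        if unknown:
            raise KeyError(
                f"unknown test name(s) {sorted(unknown)} for battery {self.label!r}"
            )
        tests = tuple(t for t in self.tests if t.name in keep)
        if not tests:
            raise ValueError("subset must contain at least one test")
        return Battery(tests=tests, label=f"{self.label} (subset of {len(tests)})")


# The default 10-test diagnostic set: three visuospatial working-memory span
# tests (Corsi MLVS: visual, simultaneous, sequential), handwriting quality
# and velocity (BHK), a cancellation test of selective attention measured
# for velocity and accuracy (TCM), copy and memory reproduction of the
# Rey-Osterrieth complex figure (ROCF), and the Developmental Eye Movement
# ratio score (DEM).  Memory-span and oculomotor tests are taken as pure VP;
# handwriting is predominantly VMC.
_DEFAULT_TESTS: tuple[tuple[str, int, int], ...] = (
    ("corsi_visual", 100, 0),
    ("corsi_simultaneous", 100, 0),
    ("corsi_sequential", 100, 0),
    ("bhk_quality", 30, 70),
    ("bhk_velocity", 30, 70),
    ("tcm_velocity", 80, 20),
    ("tcm_accuracy", 80, 20),
    ("rocf_copy", 70, 30),
    ("rocf_memory", 70, 30),
    ("dem_ratio", 100, 0),
)


def default_battery() -> Battery:
    """The standard 10-test VP/VMC diagnostic battery.

    Mean recruitment over the full battery is 76% VP / 24% VMC; these means
    are properties of the battery, not constants of the model.
    """
    return Battery(
        tests=tuple(TestDefinition(*row) for row in _DEFAULT_TESTS),
        label="default_vp_vmc_battery",
    )


def validate_battery(battery: Battery) -> list[str]:
    """Check battery invariants; return human-readable violations (empty = valid)."""
    violations: list[str] = []
    if not battery.tests:
        violations.append("battery has no tests")
    seen: set[str] = set()
    for t in battery.tests:
        if not t.name:
            violations.append("a test has an empty name")
        elif t.name in seen:
            violations.append(f"duplicate test name {t.name!r}")
        seen.add(t.name)
        if not (0 <= t.vp_weight <= 100):
            violations.append(f"test {t.name!r}: vp_weight {t.vp_weight} outside 0-100")
        if not (0 <= t.vmc_weight <= 100):
            violations.append(f"test {t.name!r}: vmc_weight {t.vmc_weight} outside 0-100")
        if t.vp_weight + t.vmc_weight != 100:
            violations.append(
                f"test {t.name!r}: vp_weight + vmc_weight = "
                f"{t.vp_weight + t.vmc_weight}, must equal 100"
            )
    return violations


def mean_weights(battery: Battery, administered: Iterable[str] | None = None) -> tuple[float, float]:
    """Mean VP and VMC recruitment percents over the administered tests.

    With ``administered=None`` the full battery is used.  The two returned
    values always sum to 100 because each per-test pair does.
    """
    names = battery.names if administered is None else tuple(administered)
    if not names:
        raise ValueError("administered subset must be nonempty")
    sub = battery.subset(names)
    mean_vp = float(np.mean([t.vp_weight for t in sub.tests]))
    mean_vmc = float(np.mean([t.vmc_weight for t in sub.tests]))
    return mean_vp, mean_vmc


def save_battery(battery: Battery, path: str | Path) -> None:
    """Write a battery to its JSON config format."""
    doc = {
        "label": battery.label,
        "tests": [
            {"name": t.name, "vp_weight": t.vp_weight, "vmc_weight": t.vmc_weight}
            for t in battery.tests
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_battery(path: str | Path) -> Battery:
    """Read a battery JSON config and validate it."""
    doc = json.loads(Path(path).read_text())
    battery = Battery(
        tests=tuple(
            TestDefinition(t["name"], int(t["vp_weight"]), int(t["vmc_weight"]))
            for t in doc["tests"]
        ),
        label=str(doc.get("label", "battery")),
    )
    violations = validate_battery(battery)
    if violations:
        raise ValueError(f"invalid battery config {path}: " + "; ".join(violations))
    return battery


# ---------------------------------------------------------------------------
# 2. scoring -- eta/mu indices, expected baselines, classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectSession:
    """One subject's z-scores at one time point; missing tests are absent keys."""

    subject_id: str
    session: str
    z_scores: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.z_scores:
            raise ValueError(
                f"session {self.session!r} of subject {self.subject_id!r} has no z-scores"
            )


class DeficitClass(str, Enum):
    """Qualitative deficit profile derived from delta_eta / delta_mu."""

    VP_PREVALENT = "VP_PREVALENT"
    VMC_PREVALENT = "VMC_PREVALENT"
    BALANCED = "BALANCED"


@dataclass(frozen=True)
class EtaMuResult:
    """All derived quantities for one scored session.

    Indices are in arbitrary units (percent-weight x z).  ``classification``
    applies the delta rule at ``tolerance``: VP_PREVALENT if
    delta_eta > tolerance, VMC_PREVALENT if delta_mu > tolerance, BALANCED
    otherwise (boundary inclusive).  ``warnings`` carries data-quality flags
    (outlying |z|, positive average z) without aborting the computation.
    """

    subject_id: str
    session: str
    n_tests: int
    avg_z: float
    eta: float
    mu: float
    eta_exp: float
    mu_exp: float
    delta_eta: float
    delta_mu: float
    mean_vp: float
    mean_vmc: float
    classification: DeficitClass
    tolerance: float
    warnings: tuple[str, ...] = ()


def _check_session(session: SubjectSession, battery: Battery) -> Battery:
    unknown = set(session.z_scores) - set(battery.names)
    if unknown:
        raise KeyError(
            f"subject {session.subject_id!r} session {session.session!r}: "
            f"test name(s) {sorted(unknown)} not in battery {battery.label!r}"
        )
    return battery.subset(session.z_scores.keys())


def average_z(session: SubjectSession) -> float:
    """Arithmetic mean z-score over the administered tests only."""
    return float(np.mean(list(session.z_scores.values())))


def compute_eta(session: SubjectSession, battery: Battery) -> float:
    """VP impairment index: eta = -sum(VP_n * z_n) / n over administered tests."""
    sub = _check_session(session, battery)
    n = len(sub.tests)
    return float(-sum(t.vp_weight * session.z_scores[t.name] for t in sub.tests) / n)


def compute_mu(session: SubjectSession, battery: Battery) -> float:
    """VMC impairment index: mu = -sum(VMC_n * z_n) / n over administered tests."""
    sub = _check_session(session, battery)
    n = len(sub.tests)
    return float(-sum(t.vmc_weight * session.z_scores[t.name] for t in sub.tests) / n)


def expected_indices(avg_z: float, mean_vp: float, mean_vmc: float) -> tuple[float, float]:
    """Expected (eta, mu) for a subject equally impaired in VP and VMC.

    If every administered test had the same z = avg_z, the indices would be
    mean_vp * |avg_z| and mean_vmc * |avg_z|; departures from these baselines
    localise the deficit.  The weights must be the administered subset's
    means (they sum to 100).
    """
    if abs(mean_vp + mean_vmc - 100.0) > 1e-9:
        raise ValueError(
            f"mean_vp + mean_vmc must equal 100, got {mean_vp + mean_vmc}"
        )
    return mean_vp * abs(avg_z), mean_vmc * abs(avg_z)


def score_session(
    session: SubjectSession,
    battery: Battery,
    tolerance: float = DEFAULT_TOLERANCE,
) -> EtaMuResult:
    """Score one session: indices, expected baselines, deltas, classification.

    A positive average z (above-norm mean performance) makes the |z| in the
    expected-value formulas break the delta complementarity; the formulas
    are still evaluated as written, but the result is flagged "no net
    impairment" and classified BALANCED rather than read as a deficit.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    avg = average_z(session)
    eta = compute_eta(session, battery)
    mu = compute_mu(session, battery)
    mean_vp, mean_vmc = mean_weights(battery, session.z_scores.keys())
    eta_exp, mu_exp = expected_indices(avg, mean_vp, mean_vmc)
    delta_eta = eta - eta_exp
    delta_mu = mu - mu_exp

    warnings: list[str] = []
    for name, z in session.z_scores.items():
        if abs(z) > Z_OUTLIER_THRESHOLD:
            msg = (
                f"subject {session.subject_id!r} session {session.session!r}: "
                f"|z| = {abs(z):.2f} on {name!r} exceeds {Z_OUTLIER_THRESHOLD:g}; "
                "value looks implausible for an age-normed test"
            )
            warnings.append(msg)
            logger.warning(msg)
    if len(session.z_scores) < len(battery.tests):
        msg = (
            f"subject {session.subject_id!r} session {session.session!r}: "
            f"incomplete battery ({len(session.z_scores)}/{len(battery.tests)} tests); "
            "expected values use the administered subset's mean weights"
        )
        warnings.append(msg)
        logger.warning(msg)

    if avg > 0:
        msg = (
            f"subject {session.subject_id!r} session {session.session!r}: "
            f"average z = {avg:.2f} > 0, no net impairment; "
            "delta indices are not interpreted as a deficit"
        )
        warnings.append(msg)
        logger.warning(msg)
        classification = DeficitClass.BALANCED
    elif delta_eta > tolerance:
        classification = DeficitClass.VP_PREVALENT
    elif delta_mu > tolerance:
        classification = DeficitClass.VMC_PREVALENT
    else:
        classification = DeficitClass.BALANCED

    return EtaMuResult(
        subject_id=session.subject_id,
        session=session.session,
        n_tests=len(session.z_scores),
        avg_z=avg,
        eta=eta,
        mu=mu,
        eta_exp=eta_exp,
        mu_exp=mu_exp,
        delta_eta=delta_eta,
        delta_mu=delta_mu,
        mean_vp=mean_vp,
        mean_vmc=mean_vmc,
        classification=classification,
        tolerance=tolerance,
        warnings=tuple(warnings),
    )


def model_lines(
    mean_vp: float, mean_vmc: float, z_grid: Sequence[float]
) -> pd.DataFrame:
    """Reference lines eta_exp(z) and mu_exp(z) for plotting.

    Both expected indices are linear in |avg_z| with slopes mean_vp and
    mean_vmc; an observed (eta, mu) point plotted against these two lines
    shows at a glance which domain exceeds its balanced share.
    """
    if len(z_grid) == 0:
        raise ValueError("z_grid must be nonempty")
    rows = [(z, *expected_indices(z, mean_vp, mean_vmc)) for z in z_grid]
    return pd.DataFrame(rows, columns=["avg_z", "eta_exp", "mu_exp"])


# ---------------------------------------------------------------------------
# 3. cohort -- summaries and pre/post comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSummary:
    """Median and Tukey-hinge interquartile bounds of per-subject average z."""

    n_subjects: int
    median_avg_z: float
    lower_hinge: float
    upper_hinge: float


@dataclass(frozen=True)
class SessionComparison:
    """Paired pre/post derived quantities for one subject.

    Improvements are relative reductions of the index,
    100 x (pre - post) / pre, reported only when the pre index is positive.
    ``paired_p`` is a two-sided exact Wilcoxon signed-rank p-value on the
    per-test z-score pairs shared between the sessions (1.0 when every
    difference is zero, where the statistic is undefined).
    """

    subject_id: str
    pre: EtaMuResult
    post: EtaMuResult
    eta_improvement: float | None
    mu_improvement: float | None
    avg_z_change: float
    paired_p: float
    n_paired: int


def tukey_hinges(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, lower hinge, upper hinge) of *values*.

    The hinges are the medians of the lower and upper halves of the sorted
    data; for odd n the overall median element belongs to neither half.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 values for hinges")
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    lower, upper = v[: n // 2], v[(n + 1) // 2 :]
    return float(np.median(v)), float(np.median(lower)), float(np.median(upper))


def cohort_summary(results: Sequence[EtaMuResult]) -> CohortSummary:
    """Tukey-hinge summary of the cohort's per-session average z-scores."""
    if len(results) < 2:
        raise ValueError("need at least 2 scored sessions for a cohort summary")
    med, lo, hi = tukey_hinges([r.avg_z for r in results])
    return CohortSummary(
        n_subjects=len(results), median_avg_z=med, lower_hinge=lo, upper_hinge=hi
    )


def _relative_reduction(pre: float, post: float) -> float | None:
    return 100.0 * (pre - post) / pre if pre > 0 else None


def compare_sessions(
    pre: SubjectSession,
    post: SubjectSession,
    battery: Battery,
    tolerance: float = DEFAULT_TOLERANCE,
) -> SessionComparison:
    """Pre/post comparison over the tests shared by the two sessions.

    Both sessions are rescored against the battery restricted to the shared
    tests (so the expected-value weights match), relative eta/mu reductions
    are computed, and a paired signed-rank test is run on the per-test
    z-score pairs.
    """
    if pre.subject_id != post.subject_id:
        raise ValueError(
            f"subject mismatch: {pre.subject_id!r} (pre) vs {post.subject_id!r} (post)"
        )
    shared = [n for n in battery.names if n in pre.z_scores and n in post.z_scores]
    if not shared:
        raise ValueError(
            f"subject {pre.subject_id!r}: sessions share no administered tests"
        )
    pre_shared = SubjectSession(
        pre.subject_id, pre.session, {n: pre.z_scores[n] for n in shared}
    )
    post_shared = SubjectSession(
        post.subject_id, post.session, {n: post.z_scores[n] for n in shared}
    )
    r_pre = score_session(pre_shared, battery, tolerance)
    r_post = score_session(post_shared, battery, tolerance)

    diffs = np.array([post.z_scores[n] - pre.z_scores[n] for n in shared])
    if np.all(diffs == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)

    return SessionComparison(
        subject_id=pre.subject_id,
        pre=r_pre,
        post=r_post,
        eta_improvement=_relative_reduction(r_pre.eta, r_post.eta),
        mu_improvement=_relative_reduction(r_pre.mu, r_post.mu),
        avg_z_change=r_post.avg_z - r_pre.avg_z,
        paired_p=p,
        n_paired=len(shared),
    )


# ---------------------------------------------------------------------------
# 4. synthetic -- generative simulator and parameter recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImpairmentProfile:
    """Ground-truth impairment of a simulated subject.

    Severities are in z units per unit recruitment: a test with weights
    (vp, vmc) yields z = -(vp_severity*vp + vmc_severity*vmc)/100 plus
    Gaussian measurement noise.  A balanced profile (vp_severity ==
    vmc_severity = s) therefore scores z = -s on every test, the "ideal
    subject" whose deltas vanish.
    """

    vp_severity: float
    vmc_severity: float
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vp_severity < 0 or self.vmc_severity < 0 or self.noise_sd < 0:
            raise ValueError("severities and noise_sd must be nonnegative")


def simulate_session(
    profile: ImpairmentProfile,
    battery: Battery,
    subject_id: str = "sim",
    session_label: str = "sim",
) -> SubjectSession:
    """Draw one synthetic session from the generative model (seeded)."""
    rng = np.random.default_rng(profile.seed)
    z = {}
    for t in battery.tests:
        signal = -(profile.vp_severity * t.vp_weight + profile.vmc_severity * t.vmc_weight) / 100.0
        z[t.name] = float(signal + rng.normal(0.0, profile.noise_sd))
    return SubjectSession(subject_id=subject_id, session=session_label, z_scores=z)


def simulate_cohort(
    profiles: Sequence[ImpairmentProfile],
    battery: Battery,
    missing_rate: float = 0.0,
    session_label: str = "sim",
) -> list[SubjectSession]:
    """Independent synthetic sessions, one per profile.

    Each test is independently dropped with probability ``missing_rate``
    (emulating refusals); a draw that would empty a subject's battery is
    redrawn, so every session keeps at least one test.  Each subject's
    stream is seeded from its own profile seed, so results do not depend on
    cohort order.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    sessions = []
    for i, profile in enumerate(profiles):
        full = simulate_session(profile, battery, subject_id=f"sim{i + 1:04d}",
                                session_label=session_label)
        if missing_rate == 0.0:
            sessions.append(full)
            continue
        # separate child stream so the mask does not disturb the noise draws
        mask_rng = np.random.default_rng(np.random.SeedSequence(profile.seed).spawn(1)[0])
        names = list(full.z_scores)
        keep = mask_rng.random(len(names)) >= missing_rate
        while not keep.any():
            keep = mask_rng.random(len(names)) >= missing_rate
        sessions.append(
            SubjectSession(
                subject_id=full.subject_id,
                session=full.session,
                z_scores={n: full.z_scores[n] for n, k in zip(names, keep) if k},
            )
        )
    return sessions


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of a classification parameter-recovery experiment."""

    true_class: DeficitClass
    n_subjects: int
    rates: Mapping[str, float]
    #: Pearson r between |delta_eta| and |avg_z| across subjects; near zero
    #: supports the claim that the detected imbalance is independent of the
    #: subject's overall degree of impairment.  NaN when either is constant.
    abs_delta_vs_severity_r: float


def _true_class(vp_severity: float, vmc_severity: float) -> DeficitClass:
    if vp_severity > vmc_severity:
        return DeficitClass.VP_PREVALENT
    if vmc_severity > vp_severity:
        return DeficitClass.VMC_PREVALENT
    return DeficitClass.BALANCED


def recovery_experiment(
    n_subjects: int,
    vp_severity: float,
    vmc_severity: float,
    noise_sd: float,
    tolerance: float = DEFAULT_TOLERANCE,
    seed: int = 0,
    battery: Battery | None = None,
) -> RecoveryResult:
    """Simulate, score and classify a cohort with a known impairment profile.

    Reports the fraction of subjects assigned to each deficit class and the
    correlation between |delta_eta| and |avg_z| across subjects.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    battery = battery or default_battery()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2**31)
    profiles = [
        ImpairmentProfile(vp_severity, vmc_severity, noise_sd, seed=int(s))
        for s in child_seeds
    ]
    sessions = simulate_cohort(profiles, battery)
    results = [score_session(s, battery, tolerance) for s in sessions]
    counts = {c.value: 0 for c in DeficitClass}
    for r in results:
        counts[r.classification.value] += 1
    rates = {c: counts[c] / n_subjects for c in counts}
    abs_delta = np.array([abs(r.delta_eta) for r in results])
    abs_avg = np.array([abs(r.avg_z) for r in results])
    if n_subjects < 2 or np.ptp(abs_delta) == 0 or np.ptp(abs_avg) == 0:
        r_val = float("nan")
    else:
        r_val = float(stats.pearsonr(abs_delta, abs_avg).statistic)
    return RecoveryResult(
        true_class=_true_class(vp_severity, vmc_severity),
        n_subjects=n_subjects,
        rates=rates,
        abs_delta_vs_severity_r=r_val,
    )


# ---------------------------------------------------------------------------
# 5. io -- tidy tables, shipped reference data, reports
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ("subject_id", "session", "test_name", "z_score")


def _parse_z(raw: str) -> tuple[float, bool]:
    """Parse a z value, accepting the European decimal comma ("41,98")."""
    s = str(raw).strip()
    normalized = False
    if "," in s and "." not in s:
        s = s.replace(",", ".")
        normalized = True
    return float(s), normalized


def read_subject_table(path: str | Path, battery: Battery | None = None,
                       strict: bool = False) -> list[SubjectSession]:
    """Read a tidy subject table CSV into sessions.

    Expected header: ``subject_id,session,test_name,z_score``.  Rows are
    grouped by (subject_id, session); duplicate (subject, session, test)
    keys are errors.  When a battery is given, unknown test names raise in
    strict mode and warn otherwise.  Decimal commas in z_score are accepted
    and normalized with a warning.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.empty:
        raise ValueError(f"{path}: empty subject table")
    missing_cols = set(TABLE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing column(s) {sorted(missing_cols)}")

    dup = df.duplicated(subset=["subject_id", "session", "test_name"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate entry for subject {row.subject_id!r}, "
            f"session {row.session!r}, test {row.test_name!r}"
        )

    known = set(battery.names) if battery is not None else None
    sessions: dict[tuple[str, str], dict[str, float]] = {}
    order: list[tuple[str, str]] = []
    for row in df.itertuples(index=False):
        try:
            z, normalized = _parse_z(row.z_score)
        except ValueError as exc:
            raise ValueError(
                f"{path}: malformed z_score {row.z_score!r} for subject "
                f"{row.subject_id!r}, test {row.test_name!r}"
            ) from exc
        if normalized:
            logger.warning(
                "%s: decimal comma normalized to %s for subject %r test %r",
                path, z, row.subject_id, row.test_name,
            )
        if known is not None and row.test_name not in known:
            msg = (f"{path}: unknown test name {row.test_name!r} "
                   f"(subject {row.subject_id!r})")
            if strict:
                raise ValueError(msg)
            logger.warning("%s -- row skipped", msg)
            continue
        key = (str(row.subject_id), str(row.session))
        if key not in sessions:
            sessions[key] = {}
            order.append(key)
        sessions[key][str(row.test_name)] = z
    return [
        SubjectSession(subject_id=sid, session=ses, z_scores=sessions[(sid, ses)])
        for sid, ses in order
    ]


def write_subject_table(sessions: Sequence[SubjectSession], path: str | Path) -> None:
    """Write sessions to the tidy CSV format ``read_subject_table`` reads."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TABLE_COLUMNS)
        for s in sessions:
            for name, z in s.z_scores.items():
                writer.writerow([s.subject_id, s.session, name, repr(float(z))])


def read_wide_table(path: str | Path, session: str = "pre") -> list[SubjectSession]:
    """Convenience reader for wide layout: one row per subject, one column per test.

    Empty cells mark tests not administered.  Converts internally to the
    tidy representation.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: wide table needs a subject_id column")
    tests = [c for c in df.columns if c not in ("subject_id", "session")]
    sessions = []
    for row in df.itertuples(index=False):
        d = getattr(row, "_asdict", lambda: dict(zip(df.columns, row)))()
        z = {}
        for t in tests:
            val = d[t]
            if val is None or (isinstance(val, float) and np.isnan(val)) or str(val).strip() in ("", "-"):
                continue
            z[t], _ = _parse_z(val)
        sessions.append(
            SubjectSession(
                subject_id=str(d["subject_id"]),
                session=str(d.get("session", session)),
                z_scores=z,
            )
        )
    return sessions


# --- shipped reference data -------------------------------------------------
# Small CSVs under etamu/data: the published worked example and the
# four-child pilot cohort (pre- and post-rehabilitation sessions), plus a
# corrected post table: the published post table prints z = 10.72 for
# subject 1 on corsi_simultaneous, inconsistent with that column's own
# printed average (-0.21), eta (13.95) and mu (7.05); the value 1.72
# reproduces all three exactly and is presumed the intended figure.

def _data_path(name: str):
    return resources.files("etamu").joinpath("data", name)


def load_example_session() -> SubjectSession:
    """The 10-test worked example profile (avg z -1.65, eta 140.5, mu 24.5)."""
    with resources.as_file(_data_path("worked_example.csv")) as p:
        return read_subject_table(p)[0]


def load_pilot_cohort(variant: str = "pre") -> list[SubjectSession]:
    """Sessions of the four-child pilot cohort.

    variant: "pre" (subject 3 has 7 of 10 tests), "post" (as published,
    including the implausible 10.72), or "post_corrected" (10.72 -> 1.72,
    see the data note above).
    """
    files = {
        "pre": "pilot_pre.csv",
        "post": "pilot_post.csv",
        "post_corrected": "pilot_post_corrected.csv",
    }
    if variant not in files:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(files)}")
    with resources.as_file(_data_path(files[variant])) as p:
        return read_subject_table(p)


# --- reports -----------------------------------------------------------------

def results_frame(results: Sequence[EtaMuResult]) -> pd.DataFrame:
    """Scored sessions as a DataFrame, numeric columns rounded to 2 decimals."""
    rows = []
    for r in results:
        rows.append(
            {
                "subject_id": r.subject_id,
                "session": r.session,
                "n_tests": r.n_tests,
                "avg_z": round(r.avg_z, 2),
                "eta": round(r.eta, 2),
                "mu": round(r.mu, 2),
                "eta_exp": round(r.eta_exp, 2),
                "mu_exp": round(r.mu_exp, 2),
                "delta_eta": round(r.delta_eta, 2),
                "delta_mu": round(r.delta_mu, 2),
                "mean_vp": round(r.mean_vp, 2),
                "mean_vmc": round(r.mean_vmc, 2),
                "classification": r.classification.value,
            }
        )
    return pd.DataFrame(rows)


def _result_dict(r: EtaMuResult) -> dict:
    d = results_frame([r]).iloc[0].to_dict()
    d["n_tests"] = int(d["n_tests"])
    d["tolerance"] = r.tolerance
    d["warnings"] = list(r.warnings)
    return d


def build_report(
    sessions: Sequence[SubjectSession],
    battery: Battery,
    tolerance: float = DEFAULT_TOLERANCE,
    comparisons: Sequence[SessionComparison] | None = None,
    z_grid: Sequence[float] | None = None,
) -> dict:
    """Assemble the full machine-readable report for a subject table.

    Every number in the report is reproducible from the input sessions and
    the battery config alone; provenance records the battery label, the
    classification tolerance and the software version.
    """
    from etamu import __version__

    results = [score_session(s, battery, tolerance) for s in sessions]
    report: dict = {
        "provenance": {
            "battery": battery.label,
            "tolerance": tolerance,
            "version": __version__,
            "warnings": [w for r in results for w in r.warnings],
        },
        "results": [_result_dict(r) for r in results],
    }
    if len(results) >= 2:
        cs = cohort_summary(results)
        report["cohort"] = {
            "n_subjects": cs.n_subjects,
            "median_avg_z": round(cs.median_avg_z, 2),
            "lower_hinge": round(cs.lower_hinge, 2),
            "upper_hinge": round(cs.upper_hinge, 2),
        }
    if comparisons:
        report["comparisons"] = [
            {
                "subject_id": c.subject_id,
                "eta_improvement": None if c.eta_improvement is None else round(c.eta_improvement, 2),
                "mu_improvement": None if c.mu_improvement is None else round(c.mu_improvement, 2),
                "avg_z_change": round(c.avg_z_change, 2),
                "paired_p": round(c.paired_p, 4),
                "n_paired": c.n_paired,
                "pre": _result_dict(c.pre),
                "post": _result_dict(c.post),
            }
            for c in comparisons
        ]
    mean_vp, mean_vmc = mean_weights(battery)
    grid = list(z_grid) if z_grid is not None else [-x / 2 for x in range(0, 9)]
    report["model_lines"] = model_lines(mean_vp, mean_vmc, grid).round(2).to_dict("records")
    return report


def render_markdown(report: dict) -> str:
    """Human-readable markdown rendering of a report dict."""
    buf = _io.StringIO()
    prov = report["provenance"]
    buf.write("# Eta-Mu report\n\n")
    buf.write(f"Battery: `{prov['battery']}` | tolerance: {prov['tolerance']} | "
              f"version: {prov['version']}\n\n")
    buf.write("## Per-session results\n\n")
    df = pd.DataFrame(report["results"])
    cols = ["subject_id", "session", "n_tests", "avg_z", "eta", "mu",
            "eta_exp", "mu_exp", "delta_eta", "delta_mu", "classification"]
    buf.write(df[cols].to_markdown(index=False))
    buf.write("\n")
    if "cohort" in report:
        c = report["cohort"]
        buf.write(
            f"\n## Cohort\n\nn = {c['n_subjects']}; median average z = "
            f"{c['median_avg_z']} (hinges {c['lower_hinge']} to {c['upper_hinge']})\n"
        )
    if "comparisons" in report:
        buf.write("\n## Pre/post comparisons\n\n")
        rows = [
            {
                "subject_id": c["subject_id"],
                "eta_improvement_%": c["eta_improvement"],
                "mu_improvement_%": c["mu_improvement"],
                "avg_z_change": c["avg_z_change"],
                "paired_p": c["paired_p"],
                "n_paired": c["n_paired"],
            }
            for c in report["comparisons"]
        ]
        buf.write(pd.DataFrame(rows).to_markdown(index=False))
        buf.write("\n")
    if prov["warnings"]:
        buf.write("\n## Warnings\n\n")
        for w in prov["warnings"]:
            buf.write(f"- {w}\n")
    return buf.getvalue()
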
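"""Synthetic multi-subject, multi-run BOLD cohorts with known ground truth.

The generator emulates the statistical regime the analysis assumes of a
resting-state cohort scanned four times over two days: each subject s has a
stable correlation structure Sigma_s, built hierarchically as a population
covariance blended with a family-level and a subject-level perturbation.
A run is drawn as

    x(t) = L_s u(t) g(t) + eps(t)

where L_s is the Cholesky factor of Sigma_s, u(t) are unit-variance latent
innovations, g(t) >= 1 is an event-gain trace equal to 1 outside
Poisson-placed bursts of gain (1 + event_amplitude), and eps is white
observation noise. Because the gain multiplies the whole latent signal,
events raise co-fluctuation amplitude brain-wide, which is exactly the
structure the RSS ranking picks up. Phenotypic targets are linear in a
subset of the true FC edges plus a confound-correlated component plus noise;
structural connectivity is drawn with Poisson rates increasing in the
population FC, so SC-FC coupling is positive by construction. Framewise
displacement is positive AR(1) noise, independent of the event gain unless
``fd_event_coupling`` is raised, which lets the RSS-motion diagnostic be
tested in both regimes.

The ``subject_snr`` knob sets the weight of the subject-specific covariance
perturbation: at 0 all subjects share one covariance (fingerprinting falls
to chance), at high values each subject is essentially their own covariance
(fingerprinting is perfect at low noise). The family weight scales with
``subject_snr`` so that the zero-SNR cohort is fully exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ets import FCMatrix, edge_index
from .preprocess import ParcellatedRun
from .sc_coupling import SCMatrix

ENCODINGS = ("A", "B")


@dataclass
class CohortConfig:
    """Generator settings.

    ``n_timepoints`` should be divisible by every bin count the downstream
    sampling strategies will request (e.g. 120 works for 4, 8, or 20 bins;
    1200 for 20 bins of 60).

    ``target_spec`` holds one (n_informative_edges, effect_size,
    confound_weight) triple per phenotypic target; effect sizes are in
    standardised units (the edge signal and the confound component are
    z-scored across subjects before weighting), and each target receives
    independent N(0, target_noise_sd^2) noise.
    """

    n_subjects: int = 20
    n_parcels: int = 20
    n_timepoints: int = 240
    n_runs: int = 4                 # 2 days x 2 phase encodings
    tr: float = 0.72
    subject_snr: float = 1.0
    event_rate: float = 4.0         # expected bursts per run
    event_amplitude: float = 1.5
    event_duration: int = 5         # frames per burst
    noise_sd: float = 0.5
    n_families: int = 5
    family_mix: float = 0.5         # family weight = family_mix * subject_snr
    target_spec: list[tuple[int, float, float]] = field(
        default_factory=lambda: [(10, 1.0, 0.3)])
    target_noise_sd: float = 1.0
    fd_base: float = 0.12           # mm, median-ish FD level
    fd_ar: float = 0.4              # AR(1) coefficient of the log-FD process
    fd_event_coupling: float = 0.0  # 0 = FD independent of the event gain
    sc_scale: float = 200.0         # Poisson rate ceiling for streamline counts
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_subjects", "n_parcels", "n_timepoints", "n_runs",
                     "n_families", "event_duration"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.n_runs % 2 != 0:
            raise ValueError("n_runs must be even (two days)")
        if self.n_families > self.n_subjects:
            raise ValueError("n_families cannot exceed n_subjects")
        for name in ("tr",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("subject_snr", "event_rate", "event_amplitude",
                     "noise_sd", "family_mix", "target_noise_sd", "fd_base",
                     "fd_event_coupling", "sc_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        n_edges = self.n_parcels * (self.n_parcels - 1) // 2
        for i, (k, eff, cw) in enumerate(self.target_spec):
            if not 0 <= k <= n_edges:
                raise ValueError(
                    f"target_spec[{i}]: n_informative_edges {k} out of range "
                    f"0..{n_edges}")


@dataclass
class SyntheticCohort:
    """Generated runs plus phenotypes, confounds, families, SC, and ground truth."""

    config: CohortConfig
    runs: dict[tuple[str, int, str], ParcellatedRun]
    fd_series: dict[tuple[str, int, str], np.ndarray]
    phenotypes: pd.DataFrame
    confounds: pd.DataFrame
    families: dict[str, int]
    sc: dict[str, SCMatrix]
    truth: dict

    @property
    def subjects(self) -> list[str]:
        return list(self.phenotypes.index)

    def true_fc(self, subject: str) -> FCMatrix:
        return FCMatrix(self.truth["sigma"][subject],
                        provenance={"subject": subject, "level": "truth"})

    def true_fc_features(self) -> np.ndarray:
        """Subject x edge matrix of ground-truth FC upper triangles."""
        return np.vstack([self.true_fc(s).vec for s in self.subjects])


def _random_correlation(rng: np.random.Generator, p: int,
                        strength: float = 1.0) -> np.ndarray:
    a = rng.standard_normal((p, max(p // 2, 2)))
    s = strength * (a @ a.T) / a.shape[1] + np.eye(p)
    d = 1.0 / np.sqrt(np.diag(s))
    return s * np.outer(d, d)


def _to_correlation(s: np.ndarray) -> np.ndarray:
    d = 1.0 / np.sqrt(np.diag(s))
    return s * np.outer(d, d)


def _event_gain(rng: np.random.Generator, t: int, rate: float,
                amplitude: float, duration: int) -> np.ndarray:
    g = np.ones(t)
    n_events = rng.poisson(rate)
    starts = np.sort(rng.integers(0, t, size=n_events))
    for s in starts:
        g[s: s + duration] = 1.0 + amplitude
    return g


def _fd_trace(rng: np.random.Generator, t: int, cfg: CohortConfig,
              gain: np.ndarray) -> np.ndarray:
    a = np.empty(t)
    a[0] = rng.standard_normal()
    innov = rng.standard_normal(t) * np.sqrt(1 - cfg.fd_ar ** 2)
    for i in range(1, t):
        a[i] = cfg.fd_ar * a[i - 1] + innov[i]
    fd = cfg.fd_base * np.exp(0.4 * a)
    if cfg.fd_event_coupling > 0:
        fd = fd * (1.0 + cfg.fd_event_coupling * (gain - 1.0))
    return fd


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full cohort; the seed in the config determines every byte."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    p, t = cfg.n_parcels, cfg.n_timepoints
    subjects = [f"sub-{i:03d}" for i in range(cfg.n_subjects)]
    families = {s: i % cfg.n_families for i, s in enumerate(subjects)}

    sigma_pop = _random_correlation(rng, p)
    fam_pert = {f: rng.standard_normal((p, max(p // 2, 2)))
                for f in range(cfg.n_families)}
    w_f = cfg.family_mix * cfg.subject_snr
    w_s = cfg.subject_snr

    sigma: dict[str, np.ndarray] = {}
    chol: dict[str, np.ndarray] = {}
    for s in subjects:
        bf = fam_pert[families[s]]
        bs = rng.standard_normal((p, max(p // 2, 2)))
        raw = (sigma_pop
               + w_f * (bf @ bf.T) / bf.shape[1]
               + w_s * (bs @ bs.T) / bs.shape[1])
        sig = _to_correlation(raw)
        sigma[s] = sig
        # small ridge keeps the factorisation stable for near-singular blends
        chol[s] = np.linalg.cholesky(sig + 1e-10 * np.eye(p))

    runs: dict[tuple[str, int, str], ParcellatedRun] = {}
    fd_series: dict[tuple[str, int, str], np.ndarray] = {}
    gains: dict[tuple[str, int, str], np.ndarray] = {}
    for s in subjects:
        for day in (1, 2):
            for enc in ENCODINGS[: cfg.n_runs // 2]:
                g = _event_gain(rng, t, cfg.event_rate, cfg.event_amplitude,
                                cfg.event_duration)
                u = rng.standard_normal((p, t))
                x = (chol[s] @ u) * g
                x = x.T + cfg.noise_sd * rng.standard_normal((t, p))
                key = (s, day, enc)
                runs[key] = ParcellatedRun(data=x, tr=cfg.tr, subject_id=s,
                                           day=day, encoding=enc)
                fd_series[key] = _fd_trace(rng, t, cfg, g)
                gains[key] = g

    # confounds: age, sex, per-subject mean FD
    age = rng.uniform(22, 37, size=cfg.n_subjects)
    sex = rng.integers(0, 2, size=cfg.n_subjects).astype(float)
    fd_mean = np.array([
        np.mean([fd_series[(s, d, e)].mean()
                 for d in (1, 2) for e in ENCODINGS[: cfg.n_runs // 2]])
        for s in subjects
    ])
    confounds = pd.DataFrame(
        {"age": age, "sex": sex, "fd_mean": fd_mean}, index=subjects)

    # phenotypes: linear in true FC edges + confound component + noise
    n_edges = p * (p - 1) // 2
    true_feat = np.vstack([sigma[s][np.triu_indices(p, k=1)] for s in subjects])
    conf_std = (confounds - confounds.mean()) / confounds.std(ddof=0).replace(0, 1)
    pheno = {}
    truth_targets = []
    for ti, (k, effect, conf_w) in enumerate(cfg.target_spec):
        edges = rng.choice(n_edges, size=k, replace=False) if k else np.array([], int)
        beta = rng.standard_normal(k)
        signal = true_feat[:, edges] @ beta if k else np.zeros(cfg.n_subjects)
        if k and signal.std() > 0:
            signal = (signal - signal.mean()) / signal.std()
        conf_dir = rng.standard_normal(conf_std.shape[1])
        conf_sig = conf_std.values @ conf_dir
        if conf_sig.std() > 0:
            conf_sig = (conf_sig - conf_sig.mean()) / conf_sig.std()
        noise = cfg.target_noise_sd * rng.standard_normal(cfg.n_subjects)
        name = f"target_{ti}"
        pheno[name] = effect * signal + conf_w * conf_sig + noise
        truth_targets.append({"name": name, "edges": edges, "beta": beta,
                              "effect_size": effect, "confound_weight": conf_w})
    phenotypes = pd.DataFrame(pheno, index=subjects)

    # structural connectivity: Poisson counts with rate increasing in pop FC
    iu = np.triu_indices(p, k=1)
    rate = cfg.sc_scale * (sigma_pop[iu] + 1.0) / 2.0
    sc: dict[str, SCMatrix] = {}
    for s in subjects:
        counts = rng.poisson(rate).astype(float)
        m = np.zeros((p, p))
        m[iu] = counts
        m.T[iu] = counts
        sc[s] = SCMatrix(m)

    truth = {"sigma": sigma, "sigma_pop": sigma_pop, "event_gain": gains,
             "targets": truth_targets, "edge_index": edge_index(p)}
    return SyntheticCohort(config=cfg, runs=runs, fd_series=fd_series,
                           phenotypes=phenotypes, confounds=confounds,
                           families=families, sc=sc, truth=truth)


TINY_CONFIG = CohortConfig(
    n_subjects=6, n_parcels=10, n_timepoints=120, n_runs=4, tr=0.72,
    subject_snr=2.0, event_rate=3.0, event_amplitude=1.5, noise_sd=0.3,
    n_families=3, target_spec=[(5, 1.0, 0.3)], seed=20_240_711,
)

# hand-computable pair: anti-correlated parcels, ETS = [-1.5, 0, -1.5]
_WORKED_RUN = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])


def make_fixture(name: str) -> SyntheticCohort:
    """Deterministic cohorts for tests and examples.

    "tiny": 6 subjects x 10 parcels x 120 timepoints x 4 runs, fixed seed.
    "worked": one subject whose every run is the 3-frame, 2-parcel matrix
    with perfectly anti-correlated parcels used in hand-worked examples.
    """
    if name == "tiny":
        return generate_cohort(replace(TINY_CONFIG))
    if name == "worked":
        cfg = CohortConfig(n_subjects=1, n_parcels=2, n_timepoints=3,
                           n_runs=4, tr=1.0, n_families=1,
                           target_spec=[], seed=0)
        runs = {}
        fd = {}
        for day in (1, 2):
            for enc in ENCODINGS:
                key = ("sub-000", day, enc)
                runs[key] = ParcellatedRun(data=_WORKED_RUN.copy(), tr=1.0,
                                           subject_id="sub-000", day=day,
                                           encoding=enc)
                fd[key] = np.full(3, 0.1)
        phenotypes = pd.DataFrame(index=["sub-000"])
        confounds = pd.DataFrame(
            {"age": [30.0], "sex": [0.0], "fd_mean": [0.1]}, index=["sub-000"])
        sc_m = np.array([[0.0, 1.0], [1.0, 0.0]])
        truth = {"sigma": {"sub-000": np.array([[1.0, -1.0], [-1.0, 1.0]])},
                 "ets": np.array([[-1.5], [0.0], [-1.5]]),
                 "targets": [], "edge_index": [(0, 1)]}
        return SyntheticCohort(config=cfg, runs=runs, fd_series=fd,
                               phenotypes=phenotypes, confounds=confounds,
                               families={"sub-000": 0},
                               sc={"sub-000": SCMatrix(sc_m)}, truth=truth)
    raise ValueError(f"unknown fixture {name!r} (expected 'tiny' or 'worked')")
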
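"""Synthetic synchronized ECG + phonocardiogram generation with ground truth.

The generator produces the two signal classes the analysis pipeline
consumes:

* **Waveform subjects** — a template P-QRS-T ECG at 500 Hz plus a
  phonocardiogram at 2,000 Hz whose S1 burst, and A2/P2 sub-components of
  S2, are placed so the five timing indices (S2 splitting, S1-S2,
  S1-S2/RR, EMAT, EMAT/RR) have known per-beat values. Heart-sound bursts
  are decaying sinusoids with a fast Gaussian attack, giving the envelope
  an unambiguous peak at the placed fiducial. Respiration modulates the
  instantaneous S2 split (controls) or leaves it essentially fixed (ASD),
  and optionally modulates burst amplitude so respiratory phase can be
  re-estimated from the acoustic channel alone.

* **Index-level cohorts** — per-subject index values drawn from group
  normal marginals (means and SDs of the reference pediatric cohort:
  50 children with secundum atrial septal defect, 50 matched controls),
  with optional correlated echocardiographic covariates (defect size,
  right-ventricular end-diastolic volume index).

Every random draw derives from a single integer seed through
``numpy.random.SeedSequence``, so identical seeds give byte-identical
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .preprocess import ECG_FS, PCG_FS, SyncRecording

__all__ = [
    "GroundTruth",
    "CohortSpec",
    "generate_ecg",
    "generate_pcg",
    "generate_subject",
    "generate_cohort_indices",
    "default_cohort_spec",
    "INDEX_COLUMNS",
    "INDEX_MARGINALS",
    "DEMOGRAPHIC_MARGINALS",
]

INDEX_COLUMNS = ["s2_split_ms", "s1s2_ms", "s1s2_rr_pct", "emat_ms", "emat_rr_pct"]

#: group marginals (mean, SD) for the five indices in the reference cohort
INDEX_MARGINALS = {
    "control": {
        "s2_split_ms": (28.20, 8.91),
        "s1s2_ms": (243.54, 26.25),
        "s1s2_rr_pct": (34.47, 2.99),
        "emat_ms": (95.16, 3.58),
        "emat_rr_pct": (15.44, 3.38),
    },
    "ASD": {
        "s2_split_ms": (39.65, 8.37),
        "s1s2_ms": (238.50, 29.72),
        "s1s2_rr_pct": (37.53, 2.39),
        "emat_ms": (96.20, 4.34),
        "emat_rr_pct": (15.33, 2.81),
    },
}

#: demographics (mean, SD) per group
DEMOGRAPHIC_MARGINALS = {
    "control": {
        "age_yr": (8.1, 2.5),
        "height_cm": (135.6, 8.3),
        "weight_kg": (31.3, 4.1),
        "bmi_kg_m2": (17.00, 0.20),
        "hr_bpm": (86.0, 6.0),
        "sbp_mmhg": (103.1, 6.3),
        "dbp_mmhg": (64.3, 6.0),
    },
    "ASD": {
        "age_yr": (8.0, 2.5),
        "height_cm": (135.4, 8.2),
        "weight_kg": (31.1, 4.0),
        "bmi_kg_m2": (16.89, 0.17),
        "hr_bpm": (87.0, 6.0),
        "sbp_mmhg": (102.8, 7.8),
        "dbp_mmhg": (64.4, 5.3),
    },
}

MALE_FRACTION = {"control": 28 / 50, "ASD": 27 / 50}

#: echocardiographic covariates for the ASD group (synthetic stand-ins;
#: chosen as typical for hemodynamically significant pediatric secundum ASD)
COVARIATE_MARGINALS = {
    "ASD": {"asd_size_mm": (12.0, 4.0), "rvedvi_ml_m2": (95.0, 15.0)},
    "control": {"rvedvi_ml_m2": (65.0, 8.0)},
}

#: pairwise Pearson correlations within the ASD group
DEFAULT_CORRELATIONS = {
    "ASD": {
        ("s2_split_ms", "asd_size_mm"): 0.72,
        ("s2_split_ms", "rvedvi_ml_m2"): 0.76,
        ("s1s2_rr_pct", "asd_size_mm"): 0.65,
        ("s1s2_rr_pct", "rvedvi_ml_m2"): 0.69,
        ("s2_split_ms", "s1s2_rr_pct"): 0.50,
        ("asd_size_mm", "rvedvi_ml_m2"): 0.70,
    },
    "control": {},
}

# --- ECG template anchors (ms relative to the R peak) -----------------------
# Gaussian bumps; widths keep most spectral energy inside the 0.5-40 Hz
# acquisition band so filtering does not materially reshape the QRS.
_ECG_WAVES = (
    # (amplitude, center_ms, sigma_ms)
    (0.15, -160.0, 25.0),  # P
    (-0.10, -24.0, 6.0),  # Q
    (1.00, 0.0, 8.0),  # R
    (-0.25, 18.0, 6.0),  # S
    (0.30, 220.0, 45.0),  # T
)
#: Q-wave onset anchor: tangent-method onset of a Gaussian limb is
#: (center - 2*sigma), the template's declared ground truth
Q_ONSET_OFFSET_MS = _ECG_WAVES[1][1] - 2.0 * _ECG_WAVES[1][2]

# --- heart-sound burst morphology -------------------------------------------
S1_FREQ_HZ = 60.0  # within the 30-120 Hz S1 band
S2_FREQ_HZ = 110.0  # within the 50-200 Hz S2 band
S1_AMP, A2_AMP, P2_AMP = 1.0, 0.60, 0.42
S1_ATTACK_MS, S1_DECAY_MS = 3.0, 15.0
S2_ATTACK_MS, S2_DECAY_MS = 1.5, 7.0


@dataclass
class GroundTruth:
    """Per-beat true fiducials and indices for a synthetic subject.

    All times are ms on the shared clock starting at 0. PCG fields are
    populated by :func:`generate_pcg`; until then they are None.
    """

    r_peak_ms: np.ndarray
    q_onset_ms: np.ndarray
    rr_ms: np.ndarray
    duration_ms: float
    s1_peak_ms: np.ndarray | None = None
    a2_peak_ms: np.ndarray | None = None
    p2_peak_ms: np.ndarray | None = None
    resp_phase: np.ndarray | None = None
    artifacts: list = field(default_factory=list)

    def __post_init__(self):
        self.r_peak_ms = np.asarray(self.r_peak_ms, dtype=float)
        self.q_onset_ms = np.asarray(self.q_onset_ms, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if np.any(np.diff(self.r_peak_ms) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.q_onset_ms >= self.r_peak_ms):
            raise ValueError("Q onset must precede the R peak")
        self._check_order()

    def _check_order(self):
        if self.s1_peak_ms is not None:
            if np.any(self.s1_peak_ms <= self.r_peak_ms):
                raise ValueError("S1 peak must follow the R peak")
            if np.any(self.a2_peak_ms <= self.s1_peak_ms):
                raise ValueError("A2 must follow the S1 peak")
            if np.any(self.p2_peak_ms < self.a2_peak_ms):
                raise ValueError("P2 must not precede A2")
        for (a, b) in self.artifacts:
            if b <= a:
                raise ValueError("artifact intervals must have positive length")

    @property
    def n_beats(self) -> int:
        return self.r_peak_ms.size

    def true_indices(self) -> pd.DataFrame:
        """Per-beat true values of the five indices."""
        if self.s1_peak_ms is None:
            raise ValueError("PCG fiducials not generated yet")
        split = self.p2_peak_ms - self.a2_peak_ms
        s1s2 = self.a2_peak_ms - self.s1_peak_ms
        emat = self.s1_peak_ms - self.q_onset_ms
        return pd.DataFrame(
            {
                "s2_split_ms": split,
                "s1s2_ms": s1s2,
                "s1s2_rr_pct": s1s2 / self.rr_ms * 100.0,
                "emat_ms": emat,
                "emat_rr_pct": emat / self.rr_ms * 100.0,
            }
        )

    def to_dict(self) -> dict:
        out = {}
        for k, v in asdict(self).items():
            out[k] = v.tolist() if isinstance(v, np.ndarray) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        kw = dict(d)
        for k in ("r_peak_ms", "q_onset_ms", "rr_ms", "s1_peak_ms",
                  "a2_peak_ms", "p2_peak_ms", "resp_phase"):
            if kw.get(k) is not None:
                kw[k] = np.asarray(kw[k], dtype=float)
        kw["artifacts"] = [tuple(a) for a in kw.get("artifacts", [])]
        return cls(**kw)


def _gauss(t, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def generate_ecg(
    heart_rate_bpm: float,
    n_beats: int,
    rr_jitter_fraction: float = 0.0,
    seed: int | None = None,
    noise_snr_db: float | None = None,
    fs: float = ECG_FS,
):
    """Template-based sinus-rhythm ECG with known Q onsets and R peaks.

    RR intervals are ``60000/heart_rate_bpm`` ms with multiplicative
    Gaussian jitter of relative SD ``rr_jitter_fraction`` (truncated at
    three sigma so intervals stay positive and physiologic).

    Returns ``(samples, GroundTruth)``.
    """
    if not (40.0 <= heart_rate_bpm <= 200.0):
        raise ValueError(f"heart rate {heart_rate_bpm} bpm outside 40-200")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    rng = np.random.default_rng(seed)
    rr_mean = 60000.0 / heart_rate_bpm
    eps = np.clip(rng.standard_normal(n_beats), -3.0, 3.0)
    rr = rr_mean * (1.0 + rr_jitter_fraction * eps)
    r_times = 400.0 + np.concatenate([[0.0], np.cumsum(rr[:-1])])
    duration_ms = r_times[-1] + 600.0
    t = np.arange(int(round(duration_ms / 1000.0 * fs))) / fs * 1000.0
    sig = np.zeros_like(t)
    for r in r_times:
        lo, hi = np.searchsorted(t, [r - 350.0, r + 420.0])
        for amp, mu, sigma in _ECG_WAVES:
            sig[lo:hi] += _gauss(t[lo:hi], amp, r + mu, sigma)
    if noise_snr_db is not None:
        rms = np.sqrt(np.mean(sig**2))
        sig = sig + rng.standard_normal(sig.size) * rms * 10 ** (-noise_snr_db / 20.0)
    gt = GroundTruth(
        r_peak_ms=r_times,
        q_onset_ms=r_times + Q_ONSET_OFFSET_MS,
        rr_ms=rr,
        duration_ms=t[-1] + 1000.0 / fs,
    )
    return sig, gt


def _burst_envelope(t_ms, center_ms, attack_ms, decay_ms):
    u = t_ms - center_ms
    env = np.zeros_like(t_ms)
    pre = (u < 0) & (u > -5 * attack_ms)
    post = (u >= 0) & (u < 10 * decay_ms)
    env[pre] = np.exp(-0.5 * (u[pre] / attack_ms) ** 2)
    env[post] = np.exp(-u[post] / decay_ms)
    return env


def generate_pcg(
    ground_truth: GroundTruth,
    s2_split_ms: float,
    emat_ms: float,
    s1s2_ms: float,
    resp_mod_ms: float = 0.0,
    resp_period_s: float = 4.0,
    noise_snr_db: float = 30.0,
    seed: int | None = None,
    beat_jitter_ms: float = 0.0,
    amp_mod_depth: float = 0.0,
    fs: float = PCG_FS,
):
    """Phonocardiogram whose burst placements invert the index definitions.

    Per beat: the S1 envelope peak sits at ``q_onset + emat_ms``; A2 at
    ``s1_peak + s1s2_ms``; P2 at ``a2 + split`` where the instantaneous
    split is ``s2_split_ms + resp_mod_ms * sin(respiratory phase)``
    (clipped at zero). ``beat_jitter_ms`` adds independent Gaussian
    beat-to-beat variation (SD, ms) to each placement interval.
    A2 and P2 share one carrier so their envelopes add coherently and the
    combined S2 envelope has local maxima exactly at the two placements.

    Returns ``(samples, GroundTruth)`` with PCG fiducials filled in.
    """
    if s2_split_ms < 0:
        raise ValueError("s2_split_ms must be >= 0")
    if emat_ms <= 0:
        raise ValueError("emat_ms must be > 0")
    if resp_mod_ms < 0:
        raise ValueError("resp_mod_ms must be >= 0")
    if 0 < s2_split_ms < 0.5:
        warnings.warn(
            f"requested split {s2_split_ms} ms is below the resolvable limit "
            f"(0.5 ms at {fs:.0f} Hz); generating anyway",
            stacklevel=2,
        )
    gt = ground_truth
    rng = np.random.default_rng(seed)
    n = gt.n_beats
    if gt.resp_phase is None:
        phase = np.mod(2 * np.pi * (gt.r_peak_ms / 1000.0) / resp_period_s, 2 * np.pi)
    else:
        phase = np.asarray(gt.resp_phase, dtype=float)

    jit = lambda: beat_jitter_ms * rng.standard_normal(n) if beat_jitter_ms else 0.0
    emat_b = emat_ms + jit()
    s1s2_b = s1s2_ms + jit()
    split_b = np.maximum(s2_split_ms + resp_mod_ms * np.sin(phase) + jit(), 0.0)

    s1 = gt.q_onset_ms + emat_b
    a2 = s1 + s1s2_b
    p2 = a2 + split_b

    t = np.arange(int(round(gt.duration_ms / 1000.0 * fs))) / fs * 1000.0
    sig = np.zeros_like(t)
    amp_fac = 1.0 - amp_mod_depth * np.cos(phase)
    for k in range(n):
        lo, hi = np.searchsorted(t, [s1[k] - 30.0, p2[k] + 120.0])
        tk = t[lo:hi]
        e1 = S1_AMP * _burst_envelope(tk, s1[k], S1_ATTACK_MS, S1_DECAY_MS)
        sig[lo:hi] += amp_fac[k] * e1 * np.cos(
            2 * np.pi * S1_FREQ_HZ * (tk - s1[k]) / 1000.0
        )
        ea = A2_AMP * _burst_envelope(tk, a2[k], S2_ATTACK_MS, S2_DECAY_MS)
        ep = P2_AMP * _burst_envelope(tk, p2[k], S2_ATTACK_MS, S2_DECAY_MS)
        carrier = np.cos(2 * np.pi * S2_FREQ_HZ * (tk - a2[k]) / 1000.0)
        sig[lo:hi] += amp_fac[k] * (ea + ep) * carrier
    if noise_snr_db is not None and np.isfinite(noise_snr_db):
        rms = np.sqrt(np.mean(sig**2))
        sig = sig + rng.standard_normal(sig.size) * rms * 10 ** (-noise_snr_db / 20.0)

    gt.s1_peak_ms = s1
    gt.a2_peak_ms = a2
    gt.p2_peak_ms = p2
    gt.resp_phase = phase
    gt._check_order()
    return sig, gt


def _resp_phase_series(t_s, period_s, hold_start_s, hold_dur_s):
    """Respiratory phase vs time: free breathing with an end-expiratory hold.

    The reference acquisition selects 30 consecutive beats at
    end-expiration, which presumes a sustained end-expiratory pause; the
    generator models guided breathing whose phase sweeps 0..2pi each cycle
    and dwells at pi (end-expiration) for ``hold_dur_s`` starting at the
    first end-expiration after ``hold_start_s``.
    """
    # first time phase hits pi at/after hold_start_s
    k = np.ceil(hold_start_s / period_s - 0.5)
    t_h = (k + 0.5) * period_s
    phase = np.empty_like(t_s)
    before = t_s < t_h
    during = (t_s >= t_h) & (t_s < t_h + hold_dur_s)
    after = t_s >= t_h + hold_dur_s
    phase[before] = 2 * np.pi * t_s[before] / period_s
    phase[during] = 2 * np.pi * t_h / period_s
    phase[after] = 2 * np.pi * (t_s[after] - hold_dur_s) / period_s
    return np.mod(phase, 2 * np.pi)


#: group defaults for waveform subjects: respiratory modulation of the S2
#: split is ~10 ms in controls and essentially absent (fixed splitting)
#: in ASD; magnitudes are package choices, the physiology fixes only the
#: contrast.
RESP_MOD_MS = {"control": 10.0, "ASD": 0.5}


def generate_subject(
    group_label: str,
    index_targets: dict | None = None,
    artifact_rate_per_min: float = 0.0,
    seed: int | None = None,
    duration_s: float = 75.0,
    n_required: int = 30,
    beat_jitter_ms: float = 2.0,
    noise_snr_db: float = 30.0,
    amp_mod_depth: float = 0.10,
    resp_period_s: float = 4.0,
):
    """Compose a full synthetic subject: ECG + PCG + ground truth.

    ``index_targets`` may supply ``s2_split_ms``, ``emat_ms``, ``s1s2_ms``
    and ``hr_bpm``; missing entries default to the group means. The
    recording includes a >= 35 s end-expiratory hold so that a run of
    ``n_required`` consecutive gated beats exists; artifact bursts (1 s of
    5x-amplitude noise) are injected at ``artifact_rate_per_min`` and
    logged in the ground truth. If artifacts leave fewer than
    ``n_required`` consecutive clean gated beats, generation is retried
    once at double duration, then raises.
    """
    if group_label not in ("ASD", "control"):
        raise ValueError("group_label must be 'ASD' or 'control'")
    targets = dict(index_targets or {})
    marg = INDEX_MARGINALS[group_label]
    split = float(targets.get("s2_split_ms", marg["s2_split_ms"][0]))
    emat = float(targets.get("emat_ms", marg["emat_ms"][0]))
    s1s2 = float(targets.get("s1s2_ms", marg["s1s2_ms"][0]))
    hr = float(targets.get("hr_bpm", DEMOGRAPHIC_MARGINALS[group_label]["hr_bpm"][0]))
    resp_mod = float(targets.get("resp_mod_ms", RESP_MOD_MS[group_label]))

    ss = np.random.SeedSequence(seed)
    for attempt, dur in enumerate([duration_s, 2 * duration_s]):
        kids = ss.spawn(3)
        seeds = [int(k.generate_state(1)[0] % (2**31)) for k in kids]
        n_beats = int(np.ceil(dur * hr / 60.0)) + 1
        ecg, gt = generate_ecg(hr, n_beats, rr_jitter_fraction=0.02, seed=seeds[0])
        # respiratory phase with an end-expiratory hold long enough to
        # cover n_required consecutive beats
        hold_dur = max(35.0, (n_required + 4) * 60.0 / hr)
        t_ecg = np.arange(int(round(gt.duration_ms / 1000.0 * ECG_FS))) / ECG_FS
        resp_series = _resp_phase_series(t_ecg, resp_period_s, 0.25 * dur, hold_dur)
        gt.resp_phase = np.interp(gt.r_peak_ms / 1000.0, t_ecg, np.unwrap(resp_series))
        gt.resp_phase = np.mod(gt.resp_phase, 2 * np.pi)
        pcg, gt = generate_pcg(
            gt,
            split,
            emat,
            s1s2,
            resp_mod_ms=resp_mod,
            resp_period_s=resp_period_s,
            noise_snr_db=noise_snr_db,
            seed=seeds[1],
            beat_jitter_ms=beat_jitter_ms,
            amp_mod_depth=amp_mod_depth,
        )
        # inject artifacts
        art_rng = np.random.default_rng(seeds[2])
        n_art = art_rng.poisson(artifact_rate_per_min * dur / 60.0)
        artifacts = []
        total_ms = gt.duration_ms
        for _ in range(n_art):
            for _try in range(50):
                start = art_rng.uniform(0.0, total_ms - 1000.0)
                if all(not (start < b and start + 1000.0 > a) for a, b in artifacts):
                    artifacts.append((float(start), float(start + 1000.0)))
                    break
        artifacts.sort()
        if artifacts:
            t_pcg = np.arange(pcg.size) / PCG_FS * 1000.0
            burst_scale = 4.0 * S1_AMP  # envelope ~5x the S1 peak
            for a, b in artifacts:
                m = (t_pcg >= a) & (t_pcg < b)
                pcg[m] += art_rng.standard_normal(int(m.sum())) * burst_scale
        gt.artifacts = artifacts

        rec = SyncRecording(
            ecg=ecg, pcg=pcg, resp_phase=np.mod(resp_series, 2 * np.pi)
        )
        # verify a clean consecutive gated run exists (against truth)
        gated = np.abs(np.angle(np.exp(1j * (gt.resp_phase - np.pi)))) <= np.pi / 4
        clean = np.array(
            [
                all(not (r + 700.0 > a and r - 150.0 < b) for a, b in artifacts)
                for r in gt.r_peak_ms
            ]
        )
        ok = gated & clean
        best = run = 0
        for flag in ok:
            run = run + 1 if flag else 0
            best = max(best, run)
        if best >= n_required:
            return rec, gt
    raise RuntimeError(
        f"could not produce {n_required} consecutive clean end-expiration beats "
        f"at artifact rate {artifact_rate_per_min}/min"
    )


@dataclass
class CohortSpec:
    """Specification for an index-level synthetic cohort.

    ``marginals[group][var] = (mean, sd)``; ``correlations[group]`` maps
    variable pairs to Pearson r. Unspecified pairs are independent.
    """

    n_per_group: dict
    marginals: dict
    correlations: dict = field(default_factory=dict)
    male_fraction: dict = field(default_factory=lambda: dict(MALE_FRACTION))
    seed: int | None = None

    def __post_init__(self):
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs n >= 2")
        for g, vars_ in self.marginals.items():
            for v, (_, sd) in vars_.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {g}/{v}")
        for g, corr in self.correlations.items():
            for pair, r in corr.items():
                if not abs(r) < 1:
                    raise ValueError(f"|r| must be < 1 for {pair}")


def default_cohort_spec(n_per_group: int = 50, seed: int | None = None,
                        covariates: bool = True) -> CohortSpec:
    """The reference-cohort spec: Table-style marginals, 50 per group."""
    marginals = {
        g: {**DEMOGRAPHIC_MARGINALS[g], **INDEX_MARGINALS[g]} for g in ("control", "ASD")
    }
    corr = {"control": {}, "ASD": {}}
    if covariates:
        for g in ("control", "ASD"):
            marginals[g] = {**marginals[g], **COVARIATE_MARGINALS.get(g, {})}
        corr = {g: dict(DEFAULT_CORRELATIONS.get(g, {})) for g in ("control", "ASD")}
    return CohortSpec(
        n_per_group={"control": n_per_group, "ASD": n_per_group},
        marginals=marginals,
        correlations=corr,
        seed=seed,
    )


def _group_draw(rng, n, marginals, correlations):
    names = list(marginals)
    k = len(names)
    corr = np.eye(k)
    for (a, b), r in correlations.items():
        if a in names and b in names:
            i, j = names.index(a), names.index(b)
            corr[i, j] = corr[j, i] = r
    ev = np.linalg.eigvalsh(corr)
    if ev.min() < -1e-10:
        raise ValueError("requested correlation matrix is not positive semidefinite")
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    z = rng.standard_normal((n, k)) @ L.T
    out = {}
    for i, name in enumerate(names):
        mean, sd = marginals[name]
        out[name] = mean + sd * z[:, i]
    return out


def generate_cohort_indices(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a subject-level cohort table from a :class:`CohortSpec`.

    Returns a DataFrame with one row per subject: ``subject_id``,
    ``group``, ``sex``, and every variable in the spec's marginals.
    Sample means/SDs converge to the spec as n grows; requested
    correlations are realized through a joint normal per group.
    """
    if seed is None:
        seed = spec.seed
    groups = sorted(spec.n_per_group.items())
    children = np.random.SeedSequence(seed).spawn(len(groups))
    frames = []
    for child, (g, n) in zip(children, groups):
        rng = np.random.default_rng(child)
        cols = _group_draw(rng, n, spec.marginals[g], spec.correlations.get(g, {}))
        df = pd.DataFrame(cols)
        df.insert(0, "group", g)
        frac = spec.male_fraction.get(g, 0.5)
        df.insert(1, "sex", np.where(rng.random(n) < frac, "male", "female"))
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(out))])
    return out
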
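"""Synthetic cohorts with planted transient co-activation structure.

Nothing here is fitted to real recordings: the generative choices (geometric
dwell times, half-cosine activation bumps, spatially smoothed Gaussian noise)
are stand-ins chosen so that every downstream stage of the analysis is
exercised against a known ground truth.

Two generation modes are provided:

* *envelope mode* (`simulate_roi_envelopes`): ROI-level amplitude frames where
  each frame is a noisy, activation-scaled copy of the currently active
  spatial template.
* *oscillation mode* (`make_lead_field` / `simulate_sensor_eeg`): alpha-band
  carriers with template-driven amplitude modulation projected to sensors
  through a random lead field, for exercising the filtering / Hilbert /
  inverse stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._util import check_rng, default_mirror_pairs, mirror_permutation
from .inverse import LeadField, SensorSeries, SourceSeries

logger = logging.getLogger(__name__)

GROUP_CYCLE = ("SM", "HO", "Other")


@dataclass
class TemplateSet:
    """Planted spatial templates with symmetry and hierarchy annotations.

    ``templates`` holds the k_true leaf templates that drive state activity;
    ``parent_templates`` holds one bilateral parent per family, equal to the
    normalized sum of its children. ``hierarchy`` maps parent row indices
    into child rows of ``templates``.
    """

    templates: np.ndarray  # (k_true, n_roi), rows centered and unit norm
    group_labels: list
    hierarchy: dict  # parent index -> list of child template indices
    mirror_spec: list  # per template: bilateral | left-dominant | right-dominant
    mirror_pairs: np.ndarray
    parent_templates: np.ndarray = None

    @property
    def k_true(self) -> int:
        return self.templates.shape[0]

    @property
    def n_roi(self) -> int:
        return self.templates.shape[1]


@dataclass
class StateSequence:
    """One state label per timeframe plus the rates the generator aimed for."""

    labels: np.ndarray  # int in [1, k]
    fs: float
    k: int
    mean_dwell_ms: np.ndarray = None
    target_rates_hz: np.ndarray = None

    @property
    def n_frames(self) -> int:
        return self.labels.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs


@dataclass
class SyntheticCohort:
    """Per-participant data plus complete generation ground truth."""

    templates: TemplateSet
    roi_env: list  # per participant (n_roi, n_frames) amplitude arrays
    states: list  # per participant StateSequence
    participant_templates: list  # per participant perturbed (k, n_roi) matrices
    participant_groups: list = None  # template group label list (shared)
    fs: float = 250.0
    config: dict = field(default_factory=dict)

    @property
    def n_participants(self) -> int:
        return len(self.roi_env)


def _smooth_half(rng, half: int, width: float) -> np.ndarray:
    """Smooth unit-norm random vector over one hemisphere's ROI indices."""
    v = gaussian_filter1d(rng.standard_normal(half), width, mode="reflect")
    v -= v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise RuntimeError("degenerate random draw")
    return v / n


def _place(n_roi, pairs, left_vals, right_vals):
    out = np.empty(n_roi)
    out[pairs[:, 0]] = left_vals
    out[pairs[:, 1]] = right_vals
    return out


def make_templates(
    n_roi: int,
    k_true: int,
    mirror_pairs: np.ndarray | None = None,
    hierarchy_depth: int = 1,
    seed=0,
    asym: float = 0.7,
    smooth_width: float = 2.0,
    unilateral_families: str = "alternate",
) -> TemplateSet:
    """Generate k_true spatial templates organized into two-child families.

    Each family derives from a bilateral, mirror-symmetric parent ``s``:

    * a *unilateral* family adds/subtracts an antisymmetric component ``m``
      so the two children are exact mirror images of each other
      (left-dominant and right-dominant);
    * a *bilateral* family adds/subtracts a symmetric component orthogonal to
      ``s`` so both children remain exactly mirror-symmetric.

    In both cases the parent equals the normalized child sum, children
    correlate more with their parent than with each other, and family bases
    are mutually orthogonalized so distinct families are well separated.
    With ``hierarchy_depth=0`` every template is an independent bilateral
    pattern and the hierarchy is empty.
    """
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    if n_roi % 2:
        raise ValueError("n_roi must be even (hemisphere-paired ROIs)")
    if mirror_pairs is None:
        mirror_pairs = default_mirror_pairs(n_roi)
    mirror_pairs = np.asarray(mirror_pairs, dtype=int)
    mirror_permutation(mirror_pairs, n_roi)  # validates the bijection
    rng = check_rng(seed)
    half = n_roi // 2

    if hierarchy_depth == 0:
        families = [(i,) for i in range(k_true)]
    else:
        families = []
        i = 0
        while i < k_true:
            if i + 1 < k_true:
                families.append((i, i + 1))
                i += 2
            else:
                families.append((i,))
                i += 1

    templates = np.zeros((k_true, n_roi))
    parents = np.zeros((len(families), n_roi))
    hierarchy: dict[int, list[int]] = {}
    mirror_spec = ["bilateral"] * k_true
    group_labels = [""] * k_true
    sym_basis: list[np.ndarray] = []  # orthogonalize family bases (half-space)

    for f, members in enumerate(families):
        s_half = _smooth_half(rng, half, smooth_width)
        for b in sym_basis:
            s_half = s_half - (s_half @ b) * b
        n = np.linalg.norm(s_half)
        if n < 1e-6:
            s_half = _smooth_half(rng, half, smooth_width)
            n = np.linalg.norm(s_half)
        s_half /= n
        sym_basis.append(s_half)
        s = _place(n_roi, mirror_pairs, s_half, s_half)
        s /= np.linalg.norm(s)
        parents[f] = s
        group = GROUP_CYCLE[f % len(GROUP_CYCLE)]
        if len(members) == 1:
            templates[members[0]] = s
            group_labels[members[0]] = group
            if hierarchy_depth > 0:
                hierarchy[f] = [members[0]]
            continue
        unilateral = unilateral_families == "all" or (
            unilateral_families == "alternate" and f % 2 == 0
        )
        if unilateral:
            m_half = _smooth_half(rng, half, smooth_width)
            m = _place(n_roi, mirror_pairs, m_half, -m_half)
            m /= np.linalg.norm(m)  # antisymmetric => orthogonal to every s
            a = s + asym * m
            b = s - asym * m  # exact mirror of a
            mirror_spec[members[0]] = "left-dominant"
            mirror_spec[members[1]] = "right-dominant"
        else:
            d_half = _smooth_half(rng, half, smooth_width)
            for bvec in sym_basis:
                d_half = d_half - (d_half @ bvec) * bvec
            d_half /= np.linalg.norm(d_half)
            sym_basis.append(d_half)
            d = _place(n_roi, mirror_pairs, d_half, d_half)
            d /= np.linalg.norm(d)
            a = s + asym * d
            b = s - asym * d
        templates[members[0]] = a / np.linalg.norm(a)
        templates[members[1]] = b / np.linalg.norm(b)
        group_labels[members[0]] = group
        group_labels[members[1]] = group
        hierarchy[f] = list(members)

    ts = TemplateSet(
        templates=templates,
        group_labels=group_labels,
        hierarchy=hierarchy,
        mirror_spec=mirror_spec,
        mirror_pairs=mirror_pairs,
        parent_templates=parents,
    )
    _validate_templates(ts)
    return ts


def _validate_templates(ts: TemplateSet) -> None:
    if np.any(ts.templates.std(axis=1) <= 0):
        raise ValueError("template with zero variance generated")
    perm = mirror_permutation(ts.mirror_pairs, ts.n_roi)
    for i, spec in enumerate(ts.mirror_spec):
        if spec == "bilateral":
            np.testing.assert_allclose(
                ts.templates[i], ts.templates[i][perm], atol=1e-12
            )


def simulate_state_sequence(
    duration_s: float,
    fs: float,
    occ_rates,
    mean_dwell_ms,
    seed=0,
    fixed_dwell: bool = False,
) -> StateSequence:
    """Semi-Markov state sequence with geometric dwells.

    States are drawn with probability proportional to ``occ_rates`` but never
    repeat back-to-back (a repeat draw would silently merge with the previous
    run and inflate dwell times past their configured mean). Dwell lengths
    are geometric with the configured per-state mean, or constant when
    ``fixed_dwell`` is set. Since the states tile the whole recording, the
    absolute configured rates are generally unattainable; they are
    renormalized, and the achievable targets are recorded on the result as
    ``target_rates_hz``.
    """
    occ_rates = np.atleast_1d(np.asarray(occ_rates, dtype=float))
    k = occ_rates.size
    mean_dwell_ms = np.broadcast_to(
        np.asarray(mean_dwell_ms, dtype=float), (k,)
    ).copy()
    mean_frames = mean_dwell_ms * fs / 1000.0
    if np.any(mean_frames < 1):
        raise ValueError("mean dwell must be at least one frame at this fs")
    if np.any(occ_rates <= 0):
        raise ValueError("occurrence rates must be positive")
    occupancy = float(np.sum(occ_rates * mean_dwell_ms / 1000.0))
    if abs(occupancy - 1.0) > 1e-9:
        logger.warning(
            "configured rates imply occupancy %.3f != 1; rates renormalized "
            "(states are exclusive and exhaustive)",
            occupancy,
        )
    q = occ_rates / occ_rates.sum()
    rng = check_rng(seed)
    n_frames = int(round(fs * duration_s))

    if k == 1:
        labels = np.ones(n_frames, dtype=int)
        target = np.array([1.0 / duration_s])
        return StateSequence(labels, fs, 1, mean_dwell_ms, target)

    # stationary distribution of the no-repeat embedded chain: pi_i ~ q_i(1-q_i)
    pi = q * (1 - q)
    pi /= pi.sum()
    mean_cycle_s = float(np.sum(pi * mean_frames)) / fs
    target_rates = pi / mean_cycle_s

    labels = np.empty(n_frames, dtype=int)
    pos = 0
    state = int(rng.choice(k, p=q))
    while pos < n_frames:
        if fixed_dwell:
            dwell = int(round(mean_frames[state]))
        else:
            dwell = int(rng.geometric(1.0 / mean_frames[state]))
        dwell = min(dwell, n_frames - pos)
        labels[pos : pos + dwell] = state + 1
        pos += dwell
        p = q.copy()
        p[state] = 0
        p /= p.sum()
        state = int(rng.choice(k, p=p))
    return StateSequence(labels, fs, k, mean_dwell_ms, target_rates)


def _activation(run_lengths: np.ndarray, a_min: float) -> np.ndarray:
    """Half-cosine bump per run, floored at a_min so activation stays > 0."""
    out = np.empty(int(run_lengths.sum()))
    pos = 0
    for L in run_lengths:
        t = (np.arange(L) + 0.5) / L
        out[pos : pos + L] = a_min + (1.0 - a_min) * np.sin(np.pi * t)
        pos += L
    return out


def _run_lengths(labels: np.ndarray) -> np.ndarray:
    change = np.flatnonzero(np.diff(labels) != 0)
    bounds = np.concatenate([[-1], change, [labels.size - 1]])
    return np.diff(bounds)


def _smooth_noise(rng, shape, width: float) -> np.ndarray:
    """Spatially correlated noise: Gaussian kernel over ROI index, unit sd."""
    noise = rng.standard_normal(shape)
    if width > 0:
        noise = gaussian_filter1d(noise, width, axis=0, mode="reflect")
        noise /= noise.std()
    return noise


def perturb_templates(
    templates: np.ndarray, sigmas, rng, smooth_width: float = 2.0
) -> np.ndarray:
    """Participant-level template copies: add scaled smooth noise, renormalize."""
    k, R = templates.shape
    out = np.empty_like(templates)
    sigmas = np.broadcast_to(np.asarray(sigmas, dtype=float), (k,))
    for i in range(k):
        eps = gaussian_filter1d(rng.standard_normal(R), smooth_width, mode="reflect")
        eps -= eps.mean()
        eps /= np.linalg.norm(eps)
        v = templates[i] + sigmas[i] * eps
        v -= v.mean()
        out[i] = v / np.linalg.norm(v)
    return out


DEFAULT_GROUP_SIGMA = {"SM": 0.1, "HO": 0.25, "Other": 0.45}


def simulate_roi_envelopes(
    templates: TemplateSet,
    states: StateSequence | None = None,
    snr: float = 0.5,
    participant_sigma_by_group: dict | None = None,
    n_participants: int = 8,
    seed=0,
    duration_s: float = 300.0,
    fs: float = 250.0,
    occ_rates=None,
    mean_dwell_ms=80.0,
    a_min: float = 0.35,
    noise_smooth_width: float = 1.0,
) -> SyntheticCohort:
    """ROI-level amplitude cohort: planted templates under transient states.

    Each participant gets an independent state sequence (same configuration;
    if ``states`` is given it supplies participant 0's sequence and its
    configuration) and a perturbed copy of every template, with perturbation
    scale set per template group by ``participant_sigma_by_group``. Frames are

        frame(t) = a(t) * template_p[state(t)] + noise(t)

    with a(t) a half-cosine activation bump per run and spatially smoothed
    Gaussian noise scaled so planted-signal variance / noise variance = snr.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if n_participants < 2:
        raise ValueError("cohort needs at least 2 participants")
    if participant_sigma_by_group is None:
        participant_sigma_by_group = dict(DEFAULT_GROUP_SIGMA)
    rng = check_rng(seed)
    k, R = templates.templates.shape
    if occ_rates is None:
        occ_rates = np.linspace(0.5, 0.9, k)
    if states is not None:
        duration_s, fs = states.duration_s, states.fs

    sigmas = np.array(
        [participant_sigma_by_group.get(g, 0.2) for g in templates.group_labels]
    )
    roi_env, seqs, part_templates = [], [], []
    for p in range(n_participants):
        if p == 0 and states is not None:
            seq = states
        else:
            seq = simulate_state_sequence(
                duration_s,
                fs,
                occ_rates,
                mean_dwell_ms,
                seed=rng.integers(2**63),
            )
        T_p = perturb_templates(templates.templates, sigmas, rng)
        a = _activation(_run_lengths(seq.labels), a_min)
        signal = a[None, :] * T_p[seq.labels - 1].T  # (R, T)
        sig_var = signal.var()
        noise = _smooth_noise(rng, signal.shape, noise_smooth_width)
        noise *= np.sqrt(sig_var / snr)
        roi_env.append(signal + noise)
        seqs.append(seq)
        part_templates.append(T_p)

    return SyntheticCohort(
        templates=templates,
        roi_env=roi_env,
        states=seqs,
        participant_templates=part_templates,
        participant_groups=list(templates.group_labels),
        fs=fs,
        config={
            "snr": snr,
            "n_participants": n_participants,
            "duration_s": duration_s,
            "fs": fs,
            "occ_rates": np.asarray(occ_rates).tolist(),
            "mean_dwell_ms": np.broadcast_to(
                np.asarray(mean_dwell_ms, float), (k,)
            ).tolist(),
            "participant_sigma_by_group": dict(participant_sigma_by_group),
            "a_min": a_min,
        },
    )


def make_lead_field(
    n_sensors: int, n_sources: int, seed=0, smooth_width: float = 2.0
) -> LeadField:
    """Random smooth full-row-rank lead field (underdetermined: m < n)."""
    if n_sensors >= n_sources:
        raise ValueError("need n_sensors < n_sources (underdetermined system)")
    rng = check_rng(seed)
    for _ in range(10):
        L = gaussian_filter1d(
            rng.standard_normal((n_sensors, n_sources)), smooth_width, axis=1
        )
        L /= np.abs(L).max()
        if np.linalg.matrix_rank(L) == n_sensors:
            return LeadField(L)
        logger.warning("rank-deficient lead field draw; regenerating")
    raise RuntimeError("could not generate a full-row-rank lead field")


def simulate_sensor_eeg(
    lead_field: LeadField,
    templates: TemplateSet,
    states: StateSequence,
    carrier_band=(8.0, 12.0),
    snr: float = 5.0,
    seed=0,
    a_min: float = 0.35,
    baseline: float = 0.1,
):
    """Sensor-level oscillation-mode data: amplitude-modulated alpha carriers.

    Source gains are the active template's loadings shifted to be
    non-negative (a shift leaves spatial correlations unchanged), modulated
    by the half-cosine activation and riding on a small ``baseline`` gain so
    every source keeps a live carrier. Each ROI template value is broadcast
    to its member source nodes (``n_sources`` must be a multiple of n_roi).

    Returns ``(SensorSeries, SourceSeries, modulation, membership)`` where
    ``modulation`` is the ground-truth (n_sources x T) envelope and
    ``membership`` maps source node index -> ROI index.
    """
    rng = check_rng(seed)
    R = templates.n_roi
    n_sources = lead_field.n_sources
    if n_sources % R:
        raise ValueError("n_sources must be a multiple of n_roi")
    nodes_per_roi = n_sources // R
    membership = np.repeat(np.arange(R), nodes_per_roi)

    fs = states.fs
    T = states.n_frames
    t = np.arange(T) / fs
    f0 = 0.5 * (carrier_band[0] + carrier_band[1])

    gains = templates.templates - templates.templates.min(axis=1, keepdims=True)
    gains = gains / gains.max(axis=1, keepdims=True)  # in [0, 1] per template
    a = _activation(_run_lengths(states.labels), a_min)
    modulation = baseline + a[None, :] * gains[states.labels - 1].T[membership]

    phases = rng.uniform(0, 2 * np.pi, n_sources)
    S = modulation * np.cos(2 * np.pi * f0 * t[None, :] + phases[:, None])
    phi = lead_field.L @ S
    if np.isfinite(snr):
        noise = rng.standard_normal(phi.shape)
        noise *= np.sqrt(phi.var() / snr)
        phi = phi + noise
    return (
        SensorSeries(phi, fs),
        SourceSeries(S, fs),
        modulation,
        membership,
    )
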
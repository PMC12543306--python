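"""Synthetic study generator with known planted effects.

Emulates the statistical structure of dense-sampling hormone-imaging
studies: one participant scanned daily for two 30-day periods (naturally
cycling, then on hormonal contraceptives) plus a small independent study
of three participants scanned roughly weekly.  Hormone trajectories follow
the canonical menstrual-cycle shape — estradiol rising to an ovulatory
peak with a smaller mid-luteal shoulder (~8-fold dynamic range) and
progesterone peaking mid-luteally (~80-fold range) — while contraceptive
users show flat, suppressed levels.

Connectomes are built at the edge level as

    tanh( backbone + dataset offset + subject offset
          + hc_effect  * hc        * HC mask
          + e2_effect  * scaled E2 * E2 mask
          + p4_effect  * scaled P4 * P4 mask
          + fd_effect  * scaled FD * motion mask
          + Gaussian noise )

where each planted mask is a connected subgraph of edges and the scaled
predictors are min-max scaled within dataset.  The backbone, planted
masks, effect coefficients, and dataset/subject offsets derive from the
ground-truth seed only, so two studies generated with the same
:class:`GroundTruthSpec` share their planted structure — which is what
makes transfer experiments between synthetic studies meaningful.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .core import Connectome, Study, edge_index, n_edges

__all__ = [
    "SubjectPlan",
    "StudyDesignSpec",
    "GroundTruthSpec",
    "HormoneSeries",
    "simulate_hormone_cycle",
    "plant_connected_component",
    "generate_study",
    "default_design",
    "default_truth",
    "canonical_networks",
]

#: Canonical large-scale functional networks used for region labelling.
CANONICAL_NETWORKS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "VentralAttention",
    "Limbic",
    "Frontoparietal",
    "Default",
)


def _rng(seed: int, *tokens) -> np.random.Generator:
    """Deterministic generator keyed on a seed plus string/int tokens."""
    entropy = [int(seed) & 0x7FFFFFFF]
    for t in tokens:
        if isinstance(t, str):
            entropy.append(zlib.crc32(t.encode()))
        else:
            entropy.append(int(t) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class SubjectPlan:
    """One subject's sampling plan within one dataset."""

    subject_id: str
    dataset_id: str
    hc_use: bool
    n_sessions: int
    interval_days: int
    cycle_length: int


@dataclass
class StudyDesignSpec:
    """Who is scanned, how often, and at what spatial resolution."""

    subjects: list[SubjectPlan]
    n_regions: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 10:
            raise ValueError("n_regions must be at least 10")
        for s in self.subjects:
            if s.n_sessions < 2:
                raise ValueError(
                    f"{s.subject_id}/{s.dataset_id}: every subject needs "
                    "at least 2 sessions"
                )
            if not 21 <= s.cycle_length <= 35:
                raise ValueError(
                    f"{s.subject_id}: cycle length {s.cycle_length} outside "
                    "the plausible [21, 35] day range"
                )
            if s.interval_days < 1:
                raise ValueError("sampling interval must be >= 1 day")


@dataclass
class GroundTruthSpec:
    """Planted effect sizes and nuisance scales, all in edge-weight units.

    ``*_edges`` give the size of each planted connected component;
    ``*_effect`` the edge-weight change per unit of the (0-1 scaled)
    predictor.  Offset scales are standard deviations of per-edge Gaussian
    offsets that are constant within a dataset or subject.  The spec's
    own ``seed`` fixes the planted masks, backbone and offsets so that
    independently generated studies can share them.
    """

    hc_edges: int = 15
    hc_effect: float = 0.6
    e2_edges: int = 15
    e2_effect: float = 0.5
    p4_edges: int = 15
    p4_effect: float = 0.5
    motion_edges: int = 10
    motion_effect: float = 0.3
    individual_scale: float = 0.15
    dataset_scale: float = 0.08
    backbone_density: float = 0.25
    backbone_scale: float = 0.35
    noise_scale: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "hc_effect",
            "e2_effect",
            "p4_effect",
            "motion_effect",
            "individual_scale",
            "dataset_scale",
            "backbone_density",
            "backbone_scale",
            "noise_scale",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.backbone_density <= 1:
            raise ValueError("backbone_density must lie in [0, 1]")


@dataclass
class HormoneSeries:
    """Hormone concentrations sampled on given cycle days."""

    day: np.ndarray
    e2: np.ndarray
    p4: np.ndarray


# Curve parameters, in fractions of cycle length.  The estradiol curve
# has an ovulatory peak near 0.46 L and a smaller mid-luteal shoulder;
# progesterone rises from a low follicular baseline to a mid-luteal peak
# near 0.75 L.  Amplitudes are set so that over a full cycle the
# max/min ratio is ~8 for estradiol and ~80 for progesterone.
_E2_BASE = 1.0
_E2_OVULATORY_AMP = 7.2
_E2_OVULATORY_LOC = 0.46
_E2_OVULATORY_WIDTH = 0.045
_E2_LUTEAL_AMP = 3.5
_E2_LUTEAL_LOC = 0.75
_E2_LUTEAL_WIDTH = 0.09
_P4_BASE = 0.15
_P4_AMP = 11.0
_P4_LOC = 0.75
_P4_WIDTH = 0.11
_HC_E2_LEVEL = 1.2
_HC_P4_LEVEL = 0.6
_JITTER_SD = 0.02
_HC_JITTER_SD = 0.05


def simulate_hormone_cycle(
    cycle_length: int,
    hc_use: bool,
    sample_days,
    seed: int = 0,
) -> HormoneSeries:
    """Estradiol/progesterone concentrations on the requested cycle days.

    Naturally-cycling trajectories are sums of Gaussian bumps on the
    cycle-day axis with an ovulatory estradiol peak near ``0.46 *
    cycle_length`` and a mid-luteal progesterone peak near ``0.75 *
    cycle_length``; contraceptive-user trajectories are flat suppressed
    levels.  A small multiplicative log-normal jitter emulates assay and
    day-to-day variability.  Deterministic given ``seed``.
    """
    if not 21 <= cycle_length <= 35:
        raise ValueError(f"cycle length {cycle_length} outside [21, 35]")
    days = np.asarray(sample_days, dtype=float)
    bad = days[(days < 0) | (days >= cycle_length)]
    if bad.size:
        raise ValueError(
            f"sample day {bad[0]:g} outside cycle [0, {cycle_length})"
        )
    rng = _rng(seed, "hormones", int(hc_use))
    if hc_use:
        e2 = np.full(days.shape, _HC_E2_LEVEL)
        p4 = np.full(days.shape, _HC_P4_LEVEL)
        jitter_sd = _HC_JITTER_SD
    else:
        L = float(cycle_length)

        def bump(loc, width):
            return np.exp(-0.5 * ((days - loc * L) / (width * L)) ** 2)

        e2 = (
            _E2_BASE
            + _E2_OVULATORY_AMP * bump(_E2_OVULATORY_LOC, _E2_OVULATORY_WIDTH)
            + _E2_LUTEAL_AMP * bump(_E2_LUTEAL_LOC, _E2_LUTEAL_WIDTH)
        )
        p4 = _P4_BASE + _P4_AMP * bump(_P4_LOC, _P4_WIDTH)
        jitter_sd = _JITTER_SD
    e2 = e2 * np.exp(rng.normal(0.0, jitter_sd, days.shape))
    p4 = p4 * np.exp(rng.normal(0.0, jitter_sd, days.shape))
    return HormoneSeries(day=days, e2=e2, p4=p4)


def plant_connected_component(
    n_regions: int, n_edges_wanted: int, seed: int = 0
) -> list[tuple[int, int]]:
    """A random connected edge set of exactly ``n_edges_wanted`` edges.

    Picks a small node set (spanning-tree first, then extra edges among
    the same nodes) so the planted component stays compact, mirroring the
    connected-component structure the downstream selection step looks
    for.  Edges are returned sorted with ``i < j``.
    """
    if n_edges_wanted < 1:
        raise ValueError("need at least one edge")
    if n_edges_wanted > n_edges(n_regions):
        raise ValueError(
            f"{n_edges_wanted} edges do not fit in a graph on "
            f"{n_regions} nodes"
        )
    rng = _rng(seed, "component")
    # Smallest node count whose complete graph holds the requested edges.
    m_min = int(np.ceil((1 + np.sqrt(1 + 8 * n_edges_wanted)) / 2))
    m_max = min(n_regions, n_edges_wanted + 1)
    if m_min > m_max:  # pragma: no cover - excluded by the size checks above
        raise ValueError("infeasible size combination")
    m = int(rng.integers(m_min, min(m_min + 3, m_max) + 1))
    nodes = rng.choice(n_regions, size=m, replace=False)
    order = rng.permutation(m)
    edges: set[tuple[int, int]] = set()
    # Random spanning tree over the chosen nodes guarantees connectivity.
    for k in range(1, m):
        a = int(nodes[order[k]])
        b = int(nodes[order[int(rng.integers(0, k))]])
        edges.add((min(a, b), max(a, b)))
    pool = [
        (int(min(a, b)), int(max(a, b)))
        for idx, a in enumerate(nodes)
        for b in nodes[idx + 1 :]
        if (min(a, b), max(a, b)) not in edges
    ]
    extra = n_edges_wanted - len(edges)
    if extra > 0:
        pick = rng.choice(len(pool), size=extra, replace=False)
        edges.update(pool[int(k)] for k in pick)
    return sorted(edges)


def default_design(n_regions: int = 50, seed: int = 0) -> StudyDesignSpec:
    """The two-study design the generator emulates.

    One subject scanned daily for 30 days naturally cycling and 30 days
    on contraceptives (60 "dense" sessions, split across two acquisition
    periods treated as separate datasets), plus three subjects scanned
    weekly for 10 sessions in total (the independent "weekly" study).
    """
    return StudyDesignSpec(
        subjects=[
            SubjectPlan("sub-01", "dense-nc", False, 30, 1, 28),
            SubjectPlan("sub-01", "dense-hc", True, 30, 1, 28),
            SubjectPlan("sub-02", "weekly", False, 4, 7, 28),
            SubjectPlan("sub-03", "weekly", True, 3, 7, 30),
            SubjectPlan("sub-04", "weekly", True, 3, 7, 26),
        ],
        n_regions=n_regions,
        seed=seed,
    )


def default_truth(seed: int = 0, **overrides) -> GroundTruthSpec:
    """Default planted-effect specification (see :class:`GroundTruthSpec`)."""
    return GroundTruthSpec(seed=seed, **overrides)


def _mask_vector(edges: list[tuple[int, int]], n_regions: int) -> np.ndarray:
    iu, ju = edge_index(n_regions)
    flat = {(i, j): k for k, (i, j) in enumerate(zip(iu, ju))}
    v = np.zeros(n_edges(n_regions))
    for i, j in edges:
        v[flat[(i, j)]] = 1.0
    return v


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(values), np.nanmax(values)
    if hi - lo <= 0:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def canonical_networks(n_regions: int) -> pd.DataFrame:
    """Region table assigning each region to one of seven canonical networks."""
    names = [f"region{k:03d}" for k in range(n_regions)]
    nets = [CANONICAL_NETWORKS[k % len(CANONICAL_NETWORKS)] for k in range(n_regions)]
    return pd.DataFrame(
        {"region_id": np.arange(n_regions), "region_name": names, "network_name": nets}
    )


def generate_study(
    design: StudyDesignSpec, truth: GroundTruthSpec
) -> tuple[Study, dict]:
    """Generate a study and the ground-truth record of its planted effects.

    Returns the :class:`~cycleconn.core.Study` (session table +
    connectomes + region/network table) and a JSON-serializable record
    holding the planted edge masks, effect coefficients and seeds.
    """
    n = design.n_regions
    ne = n_edges(n)
    labels = [f"region{k:03d}" for k in range(n)]

    masks = {
        "hc": plant_connected_component(n, truth.hc_edges, _rng(truth.seed, "hc").integers(2**31)),
        "e2": plant_connected_component(n, truth.e2_edges, _rng(truth.seed, "e2").integers(2**31)),
        "p4": plant_connected_component(n, truth.p4_edges, _rng(truth.seed, "p4").integers(2**31)),
        "motion": plant_connected_component(
            n, truth.motion_edges, _rng(truth.seed, "motion").integers(2**31)
        ),
    }
    mask_vec = {k: _mask_vector(v, n) for k, v in masks.items()}
    effects = {
        "hc": truth.hc_effect,
        "e2": truth.e2_effect,
        "p4": truth.p4_effect,
        "motion": truth.motion_effect,
    }

    bb_rng = _rng(truth.seed, "backbone")
    backbone = np.where(
        bb_rng.random(ne) < truth.backbone_density,
        bb_rng.normal(0.0, truth.backbone_scale, ne),
        0.0,
    )

    dataset_ids = sorted({s.dataset_id for s in design.subjects})
    subject_ids = sorted({s.subject_id for s in design.subjects})
    dataset_offset = {
        d: _rng(truth.seed, "dataset", d).normal(0.0, truth.dataset_scale, ne)
        for d in dataset_ids
    }
    subject_offset = {
        s: _rng(truth.seed, "subject", s).normal(0.0, truth.individual_scale, ne)
        for s in subject_ids
    }

    rows = []
    session_counter: dict[str, int] = {}
    for plan in design.subjects:
        t0 = session_counter.get(plan.subject_id, 0)
        days = (np.arange(plan.n_sessions) * plan.interval_days) % plan.cycle_length
        hormones = simulate_hormone_cycle(
            plan.cycle_length,
            plan.hc_use,
            days,
            seed=_rng(design.seed, "hormone", plan.subject_id, plan.dataset_id).integers(2**31),
        )
        fd_rng = _rng(design.seed, "fd", plan.subject_id, plan.dataset_id)
        fd = np.clip(fd_rng.normal(0.12, 0.03, plan.n_sessions), 0.02, None)
        for k in range(plan.n_sessions):
            rows.append(
                {
                    "subject_id": plan.subject_id,
                    "dataset_id": plan.dataset_id,
                    "session_id": f"ses-{t0 + k:03d}",
                    "hc_use": int(plan.hc_use),
                    "cycle_day": int(days[k]),
                    "e2": hormones.e2[k],
                    "p4": hormones.p4[k],
                    "mean_fd": fd[k],
                }
            )
        session_counter[plan.subject_id] = t0 + plan.n_sessions
    sessions = pd.DataFrame(rows)

    # Min-max scale the continuous predictors within each dataset, the
    # same convention the modeling stage uses.
    scaled = {
        col: sessions.groupby("dataset_id")[col]
        .transform(lambda v: _minmax(v.to_numpy()))
        .to_numpy()
        for col in ("e2", "p4", "mean_fd")
    }

    iu, ju = edge_index(n)
    connectomes = []
    for k, row in enumerate(sessions.itertuples()):
        noise_rng = _rng(
            design.seed, "noise", row.subject_id, row.dataset_id, row.session_id
        )
        signal = (
            backbone
            + dataset_offset[row.dataset_id]
            + subject_offset[row.subject_id]
            + effects["hc"] * row.hc_use * mask_vec["hc"]
            + effects["e2"] * scaled["e2"][k] * mask_vec["e2"]
            + effects["p4"] * scaled["p4"][k] * mask_vec["p4"]
            + effects["motion"] * scaled["mean_fd"][k] * mask_vec["motion"]
            + noise_rng.normal(0.0, truth.noise_scale, ne)
        )
        w = np.tanh(signal)
        mat = np.eye(n)
        mat[iu, ju] = w
        mat[ju, iu] = w
        connectomes.append(Connectome(labels=labels, matrix=mat))
    study = Study(sessions=sessions, connectomes=connectomes, regions=canonical_networks(n))
    record = {
        "design_seed": design.seed,
        "truth_seed": truth.seed,
        "n_regions": n,
        "masks": {k: [[int(i), int(j)] for i, j in v] for k, v in masks.items()},
        "effects": effects,
        "scales": {
            "individual": truth.individual_scale,
            "dataset": truth.dataset_scale,
            "backbone_density": truth.backbone_density,
            "backbone_scale": truth.backbone_scale,
            "noise": truth.noise_scale,
        },
        "truth": asdict(truth),
    }
    return study, record
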
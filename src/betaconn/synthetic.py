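"""Synthetic cohorts of trial-wise beta series with planted structure.

The generator emulates the study design that the pipeline analyses:
24 participants, 263 ROIs, 80 trials per condition, one passive baseline
plus four active speech-processing conditions (PN-, PN+, CN-, CN+).
Beta series are zero-mean multivariate Gaussian draws whose correlation
matrix carries a planted 4-module block structure (within-module rho_in,
between-module rho_out), a designated target node whose cross-module
connectivity layout varies by condition, and per-participant reaction
times correlated with the target node's connectivity spread in one
condition.  Only rank correlations of the betas are analysed downstream,
so mean activation levels are irrelevant and zero-mean Gaussians suffice.

Optionally, each module can contain a few "bridge" nodes whose
cross-module correlations are elevated (``rho_bridge``), forming an
inter-module core mesh.  Attaching the target's strong connections to
that mesh dissociates the three hub roles: the target's neighbours are
then mutually connected (low flow coefficient) and provide alternative
inter-module routes (low betweenness) while the even spread keeps its
participation coefficient at the top — a connector that is not also a
local or global bridge.  In a flat block model the three roles are
analytically coupled and cannot be planted independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "ACTIVE_CONDITIONS",
    "MODULE_NAMES",
    "GroundTruth",
    "SyntheticCohort",
    "default_truth",
    "connector_truth",
    "build_block_correlation",
    "nearest_psd",
    "sample_cohort",
    "generate_behavior",
    "make_reference_table",
    "roi_bookkeeping",
    "make_node_table",
]

CONDITIONS = ["baseline", "PN-", "PN+", "CN-", "CN+"]
ACTIVE_CONDITIONS = CONDITIONS[1:]
MODULE_NAMES = ["VN", "FPN", "DMN", "SAN"]

# Behavioral profile of the study cohort (accuracy proportion, mean RT ms)
BEHAVIOR_PROFILE = {
    "PN-": (0.96, 1296.0),
    "PN+": (0.92, 1413.0),
    "CN-": (0.88, 2389.0),
    "CN+": (0.63, 2575.0),
}
RT_SD = 300.0
ACC_SD = 0.05


def _default_partition(n_nodes: int = 263, n_modules: int = 4) -> np.ndarray:
    """Near-equal module sizes (66/66/66/65 for the default layout); the
    last node — the appended target ROI — is assigned to module 1 (FPN)."""
    sizes = [n_nodes // n_modules] * n_modules
    for i in range(n_nodes - sum(sizes)):
        sizes[i] += 1
    labels = np.concatenate([np.full(s, m) for m, s in enumerate(sizes)])
    if n_nodes == 263 and n_modules == 4:
        labels = np.concatenate(
            [np.full(66, 0), np.full(65, 1), np.full(66, 2), np.full(65, 3), [1]]
        )
    return labels.astype(int)


def _default_role_profile() -> dict[str, np.ndarray]:
    """Fraction of the target's strong connections placed in each module
    (VN, FPN, DMN, SAN), per condition: FPN member at baseline, connector
    anchored in the VN during perception, SAN-anchored connector during
    clear comprehension, VN-concentrated (non-connector) during noisy
    comprehension."""
    return {
        "baseline": np.array([0.05, 0.85, 0.05, 0.05]),
        "PN-": np.array([0.40, 0.20, 0.20, 0.20]),
        "PN+": np.array([0.40, 0.20, 0.20, 0.20]),
        "CN-": np.array([0.20, 0.20, 0.20, 0.40]),
        "CN+": np.array([0.85, 0.05, 0.05, 0.05]),
    }


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    partition: np.ndarray = field(default_factory=_default_partition)
    target_node: int | None = 262
    role_profile: dict[str, np.ndarray] = field(default_factory=_default_role_profile)
    rho_in: float = 0.4
    rho_out: float = 0.05
    n_trials: int = 80
    n_participants: int = 24
    behavior_r: dict[str, float] = field(
        default_factory=lambda: {"PN-": 0.0, "PN+": 0.0, "CN-": 0.0, "CN+": -0.47}
    )
    seed: int = 0
    # target-layout details
    n_strong: int = 40
    rho_target: float = 0.4
    attach: str = "spread"  # "spread" | "bridge"
    # optional bridge mesh (role-dissociation cohorts)
    n_bridge_per_module: int = 0
    rho_bridge: float = 0.0
    # per-participant jitter of the target's connectivity spread, feeding
    # the planted behavior correlation
    spread_jitter: float = 0.3

    def __post_init__(self) -> None:
        self.partition = np.asarray(self.partition, dtype=int)
        if not (0 <= self.rho_out <= self.rho_in < 1):
            raise ValueError("need 0 <= rho_out <= rho_in < 1")
        for cond, frac in self.role_profile.items():
            frac = np.asarray(frac, dtype=float)
            if frac.size != self.n_modules or not np.isclose(frac.sum(), 1.0):
                raise ValueError(
                    f"role profile for {cond!r} must have one fraction per "
                    "module and sum to 1"
                )
            self.role_profile[cond] = frac
        for r in self.behavior_r.values():
            if abs(r) > 1:
                raise ValueError("behavior correlations must be in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.partition.size

    @property
    def n_modules(self) -> int:
        return int(self.partition.max()) + 1

    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.partition, minlength=self.n_modules)

    def validate(self) -> None:
        """Strict cohort-level checks (module sizes, target index)."""
        if (self.module_sizes() < 3).any():
            raise ValueError("every module must contain at least 3 nodes")
        if self.target_node is not None and not (
            0 <= self.target_node < self.n_nodes
        ):
            raise ValueError("target node index out of range")

    def bridge_nodes(self) -> np.ndarray:
        """Indices of the per-module bridge (core-mesh) nodes."""
        if self.n_bridge_per_module == 0:
            return np.array([], dtype=int)
        out = []
        for m in range(self.n_modules):
            members = np.flatnonzero(self.partition == m)
            members = members[members != self.target_node]
            out.append(members[: self.n_bridge_per_module])
        return np.concatenate(out)


@dataclass
class SyntheticCohort:
    """Sampled beta series plus planted behavior and the ground truth."""

    beta: dict[tuple[str, str], np.ndarray]  # (participant, condition) -> trials x nodes
    behavior: pd.DataFrame  # participant, condition, rt, accuracy
    truth: GroundTruth
    node_ids: list[str]
    spread_latent: pd.DataFrame | None = None  # per-participant spread jitter

    @property
    def participants(self) -> list[str]:
        return sorted({p for p, _ in self.beta})

    @property
    def conditions(self) -> list[str]:
        seen = []
        for _, c in self.beta:
            if c not in seen:
                seen.append(c)
        return [c for c in CONDITIONS if c in seen] or seen


def default_truth(seed: int = 0, **overrides) -> GroundTruth:
    """The default study-like cohort: flat 4-module block structure."""
    return replace(GroundTruth(seed=seed), **overrides) if overrides else GroundTruth(seed=seed)


def connector_truth(seed: int = 0, **overrides) -> GroundTruth:
    """A role-dissociation cohort: bridge mesh enabled and the target's
    strong connections attached to it, planting a connector that is not
    also a local or global bridge.

    The target's connections are spread nearly evenly (slight home tilt
    so its community membership stays identifiable) over each module's
    bridge nodes; in CN+ they concentrate at home and the node stops
    being a connector, mirroring the condition-dependent role the
    pipeline is meant to detect.
    """
    base = GroundTruth(
        seed=seed,
        attach="bridge",
        n_bridge_per_module=6,
        rho_bridge=0.5,
        n_strong=27,
        rho_target=0.55,
        role_profile={
            "baseline": np.array([0.05, 0.85, 0.05, 0.05]),
            "PN-": np.array([0.55, 0.15, 0.15, 0.15]),
            "PN+": np.array([0.55, 0.15, 0.15, 0.15]),
            "CN-": np.array([0.15, 0.15, 0.15, 0.55]),
            "CN+": np.array([0.70, 0.10, 0.10, 0.10]),
        },
        spread_jitter=0.5,
    )
    return replace(base, **overrides) if overrides else base


def nearest_psd(c: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Repair a symmetric matrix to positive semidefiniteness by clipping
    negative eigenvalues at 0, then re-normalizing to unit diagonal."""
    e, v = np.linalg.eigh(c)
    if e.min() >= -tol:
        return c
    e = np.clip(e, 0.0, None)
    repaired = (v * e) @ v.T
    d = np.sqrt(np.diag(repaired))
    if (d == 0).any():
        raise ValueError("matrix not repairable to a correlation matrix")
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    repaired = (repaired + repaired.T) / 2.0
    if np.linalg.eigvalsh(repaired).min() < -1e-8:
        raise ValueError("matrix remains non-PSD after eigenvalue clipping")
    return repaired


def _allocate(counts_target: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n_strong over modules."""
    raw = fractions * counts_target
    base = np.floor(raw).astype(int)
    rem = counts_target - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def _factor_correlation(
    truth: GroundTruth, condition: str | None, spread_scale: float = 1.0
) -> np.ndarray:
    """Factor-model construction of the bridged correlation matrix.

    One latent factor per module (pairwise correlation rho_out/rho_in so
    regular nodes reproduce the flat block pattern) plus one global
    bridge factor loaded by the per-module bridge nodes, giving them
    elevated cross-module correlations (rho_bridge) — an inter-module
    core mesh.  The target's loadings are derived from the condition's
    role profile: its spread (1 - sum of squared fractions) sets the
    bridge-factor loading, its home excess sets the home-module loading.
    PSD by construction (no repair needed), which is what makes the
    planted role layouts survive into the realized matrix: patching the
    same values directly into the block matrix is far from PSD and the
    nearest-PSD repair would wash the structure back out.
    """
    part = truth.partition
    n = truth.n_nodes
    k = truth.n_modules
    g_corr = np.full((k, k), truth.rho_out / truth.rho_in)
    np.fill_diagonal(g_corr, 1.0)
    phi = np.zeros((k + 1, k + 1))
    phi[:k, :k] = g_corr
    phi[k, k] = 1.0  # bridge factor, independent of module factors

    load = np.zeros((n, k + 1))
    load[np.arange(n), part] = np.sqrt(truth.rho_in)
    bridges = truth.bridge_nodes()
    if bridges.size:
        load[bridges, k] = np.sqrt(max(truth.rho_bridge - truth.rho_out, 0.0))

    t = truth.target_node
    if t is not None and condition is not None and condition in truth.role_profile:
        frac = truth.role_profile[condition]
        home = int(np.argmax(frac))
        spread = 1.0 - float((frac**2).sum())
        max_spread = 1.0 - 1.0 / k
        w_h = min(0.85, 0.8 * (spread / max_spread) ** 1.5 * spread_scale)
        w_home = (frac[home] - 1.0 / k) / (1.0 - 1.0 / k)
        load[t] = 0.0
        load[t, home] = w_home
        load[t, k] = w_h
    c = load @ phi @ load.T
    d = np.diag(c)
    if (d > 1.0 + 1e-9).any():
        raise ValueError("factor loadings exceed unit variance")
    c = c - np.diag(d) + np.eye(n)
    return (c + c.T) / 2.0


def build_block_correlation(
    truth: GroundTruth, condition: str | None = None, spread_scale: float = 1.0
) -> np.ndarray:
    """The planted correlation matrix for one condition.

    Within-module entries are rho_in, between-module entries rho_out;
    the target node's row/column follows the condition's role profile
    (n_strong entries of rho_target allocated across modules by largest
    remainder, the rest rho_out).  The result is repaired to the nearest
    positive semidefinite correlation matrix if needed (planting
    idiosyncratic target links on top of correlated blocks is not
    exactly PSD; the repair is the documented eigenvalue-clipping one).

    With ``attach='bridge'`` the matrix is instead built from an explicit
    factor model (see :func:`_factor_correlation`), which is PSD by
    construction and carries the bridge mesh that dissociates the three
    hub roles.
    """
    if truth.attach == "bridge" and truth.n_bridge_per_module > 0:
        return _factor_correlation(truth, condition, spread_scale=spread_scale)
    part = truth.partition
    n = truth.n_nodes
    same = part[:, None] == part[None, :]
    c = np.where(same, truth.rho_in, truth.rho_out).astype(float)
    np.fill_diagonal(c, 1.0)

    t = truth.target_node
    if t is not None and condition is not None and condition in truth.role_profile:
        frac = truth.role_profile[condition]
        row = np.full(n, truth.rho_out)
        alloc = _allocate(truth.n_strong, frac)
        home = int(np.argmax(frac))
        for m in range(truth.n_modules):
            members = np.flatnonzero(part == m)
            members = members[members != t]
            chosen = members[: alloc[m]]
            value = truth.rho_target
            if m != home and spread_scale != 1.0:
                value = float(np.clip(value * spread_scale, 0.0, 0.95))
            row[chosen] = value
        row[t] = 1.0
        c[t, :] = row
        c[:, t] = row
    return nearest_psd(c)


def _chol_factor(c: np.ndarray) -> np.ndarray:
    """Sampling factor L with L @ L.T = c (eigh-based, PSD-safe)."""
    e, v = np.linalg.eigh(c)
    return v * np.sqrt(np.clip(e, 0.0, None))


def _stream(seed: int, p_idx: int, stage: int, cond: str) -> np.random.Generator:
    """Independent, reproducible RNG stream per participant x stage x
    condition (stage 0: beta draws, 1: spread latents, 2: behavior)."""
    if cond in CONDITIONS:
        cond_idx = CONDITIONS.index(cond)
    else:  # custom condition labels: stable fallback
        cond_idx = 100 + sum(ord(ch) for ch in cond) % 899
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(p_idx, stage, cond_idx))
    )


def sample_cohort(
    truth: GroundTruth,
    conditions: list[str] | None = None,
    participants: list[str] | None = None,
) -> SyntheticCohort:
    """Draw a full cohort of beta series (plus planted behavior).

    Each participant x condition matrix is an independent zero-mean
    multivariate normal draw with the condition's block correlation.  In
    conditions with a planted behavior correlation, a per-participant
    latent scales the target's cross-home connection strengths
    (``spread_jitter``) and the reaction times are generated against that
    latent, so faster participants have a more spread-out target node.
    Fully reproducible from ``truth.seed``.
    """
    conditions = list(conditions) if conditions is not None else list(CONDITIONS)
    if participants is None:
        participants = [f"sub-{i + 1:02d}" for i in range(truth.n_participants)]
    node_ids = [f"roi{i + 1:03d}" for i in range(truth.n_nodes)]
    if truth.target_node is not None:
        node_ids[truth.target_node] = "target"

    beta: dict[tuple[str, str], np.ndarray] = {}
    latent_rows = []
    behavior_rows = []
    for p_idx, pid in enumerate(participants):
        u = {
            cond: float(_stream(truth.seed, p_idx, 1, cond).normal())
            for cond in ACTIVE_CONDITIONS
        }
        for cond in conditions:
            rng = _stream(truth.seed, p_idx, 0, cond)
            scale = 1.0
            if (
                truth.target_node is not None
                and truth.behavior_r.get(cond, 0.0) != 0.0
                and truth.spread_jitter > 0
                and cond in truth.role_profile
            ):
                # per-participant latent scales the target's cross-home
                # connection strength, carrying the planted behavior link
                scale = float(np.clip(1.0 + truth.spread_jitter * u[cond], 0.2, 1.8))
            c = build_block_correlation(truth, cond, spread_scale=scale)
            L = _chol_factor(c)
            z = rng.standard_normal((truth.n_trials, truth.n_nodes))
            beta[(pid, cond)] = z @ L.T
        for cond in ACTIVE_CONDITIONS:
            if cond not in conditions:
                continue
            acc_mean, rt_mean = BEHAVIOR_PROFILE[cond]
            r = truth.behavior_r.get(cond, 0.0)
            eps, eps_acc = _stream(truth.seed, p_idx, 2, cond).normal(size=2)
            rt = rt_mean + RT_SD * (
                r * u[cond] + np.sqrt(max(0.0, 1 - r**2)) * eps
            )
            acc = float(np.clip(acc_mean + ACC_SD * eps_acc, 0.0, 1.0))
            behavior_rows.append(
                {"participant": pid, "condition": cond, "rt": rt, "accuracy": acc}
            )
            latent_rows.append(
                {"participant": pid, "condition": cond, "spread_latent": u[cond]}
            )
    behavior = pd.DataFrame(behavior_rows)
    latent = pd.DataFrame(latent_rows) if latent_rows else None
    return SyntheticCohort(
        beta=beta,
        behavior=behavior,
        truth=truth,
        node_ids=node_ids,
        spread_latent=latent,
    )


def generate_behavior(
    participation: np.ndarray,
    r_target: float,
    mean_rt: float = 2575.0,
    sd_rt: float = 300.0,
    seed: int = 0,
) -> np.ndarray:
    """Reaction times with population correlation ``r_target`` against
    the supplied per-participant participation values.

    RT = mean + sd * (r * z(P) + sqrt(1 - r^2) * noise); with r = -1 and
    hence zero noise weight the sample correlation is exactly -1.
    """
    p = np.asarray(participation, dtype=float)
    if abs(r_target) > 1:
        raise ValueError("|r_target| must be <= 1")
    if p.size < 3:
        raise ValueError("need at least 3 participants")
    sd = p.std()
    if sd == 0:
        if r_target != 0:
            raise ValueError(
                "cannot plant a nonzero correlation on zero-variance "
                "participation values"
            )
        z = np.zeros_like(p)
    else:
        z = (p - p.mean()) / sd
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(p.size)
    return mean_rt + sd_rt * (r_target * z + np.sqrt(1 - r_target**2) * noise)


# ---------------------------------------------------------------------------
# ROI bookkeeping


def make_reference_table(n: int = 264, seed: int = 0) -> pd.DataFrame:
    """A synthetic stand-in for a 264-ROI reference atlas table.

    Coordinates are drawn in an MNI-like bounding box.  One ROI sits at
    the right thalamus outside the gray-matter mask (gray_matter=False)
    and one at the left fusiform location that overlaps the target ROI,
    so the bookkeeping path can be exercised end to end.
    """
    rng = np.random.default_rng(seed)

    def _draw(k: int) -> np.ndarray:
        return np.column_stack(
            [
                rng.uniform(-70, 70, k),
                rng.uniform(-105, 70, k),
                rng.uniform(-45, 75, k),
            ]
        ).round(0)

    # keep random ROIs clear of the target location so the overlap rule
    # removes exactly the planted fusiform ROI
    target = np.array([-47.0, -55.0, -17.0])
    xyz = _draw(n)
    for _ in range(100):
        close = np.linalg.norm(xyz - target, axis=1) <= 12.0
        if not close.any():
            break
        xyz[close] = _draw(int(close.sum()))
    df = pd.DataFrame(xyz, columns=["x", "y", "z"])
    df["roi_id"] = [f"ref{i + 1:03d}" for i in range(n)]
    df["label"] = [f"region_{i + 1}" for i in range(n)]
    df["gray_matter"] = True
    # right thalamus ROI outside the gray-matter mask
    df.loc[0, ["x", "y", "z"]] = (9.0, -4.0, 6.0)
    df.loc[0, "gray_matter"] = False
    df.loc[0, "label"] = "right_thalamus"
    # left fusiform ROI overlapping the target location
    df.loc[1, ["x", "y", "z"]] = (-47.0, -51.0, -21.0)
    df.loc[1, "label"] = "left_fusiform"
    return df[["roi_id", "x", "y", "z", "label", "gray_matter"]]


def roi_bookkeeping(
    reference: pd.DataFrame,
    target_xyz: tuple[float, float, float] = (-47.0, -55.0, -17.0),
    target_label: str = "left_vOT",
    overlap_radius: float = 10.0,
) -> pd.DataFrame:
    """Assemble the analysis node set from a reference ROI table.

    Drops ROIs outside the gray-matter mask, appends the target ROI, and
    removes reference ROIs whose centers lie within ``overlap_radius`` mm
    of the target (overlapping spheres).  With the 264-ROI reference this
    yields the 263-node analysis set, the target last.
    """
    df = reference.copy()
    df = df[df["gray_matter"]].reset_index(drop=True)
    dist = np.sqrt(
        (df["x"] - target_xyz[0]) ** 2
        + (df["y"] - target_xyz[1]) ** 2
        + (df["z"] - target_xyz[2]) ** 2
    )
    df = df[dist > overlap_radius].reset_index(drop=True)
    target_row = pd.DataFrame(
        [
            {
                "roi_id": "target",
                "x": target_xyz[0],
                "y": target_xyz[1],
                "z": target_xyz[2],
                "label": target_label,
                "gray_matter": True,
            }
        ]
    )
    return pd.concat([df, target_row], ignore_index=True)


def make_node_table(truth: GroundTruth, seed: int = 0) -> pd.DataFrame:
    """Node table (id, coordinates, label, module) matching the cohort's
    node order, via the reference-atlas bookkeeping when the layout is
    the default 263-node one."""
    if truth.n_nodes == 263:
        table = roi_bookkeeping(make_reference_table(seed=seed))
    else:
        rng = np.random.default_rng(seed)
        xyz = rng.uniform(-70, 70, (truth.n_nodes, 3)).round(0)
        table = pd.DataFrame(xyz, columns=["x", "y", "z"])
        table["roi_id"] = [f"ref{i + 1:03d}" for i in range(truth.n_nodes)]
        table["label"] = [f"region_{i + 1}" for i in range(truth.n_nodes)]
        table["gray_matter"] = True
    if len(table) != truth.n_nodes:
        raise ValueError(
            f"node table has {len(table)} rows for {truth.n_nodes} nodes"
        )
    table = table.reset_index(drop=True)
    table["node_id"] = [f"roi{i + 1:03d}" for i in range(len(table))]
    if truth.target_node is not None:
        table.loc[truth.target_node, "node_id"] = "target"
    table["module"] = [
        MODULE_NAMES[m] if m < len(MODULE_NAMES) else f"M{m}"
        for m in truth.partition
    ]
    return table[["node_id", "x", "y", "z", "label", "module"]]
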
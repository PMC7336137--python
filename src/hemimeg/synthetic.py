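"""Synthetic MEG cohorts with known phase-lag coupling structure.

Real resting-state recordings are replaced by coupled narrowband
oscillators.  Each coupled edge (i, j) shares a band-limited Gaussian
carrier: the target's band component is
``sqrt(c) * (carrier of i, phase-rotated by phi) + sqrt(1-c) * noise``,
so the fraction ``c`` of shared variance and the lag ``phi`` fully
determine the expected phase-lag-index family values.  The phase lag is
applied as a frequency-domain rotation (all-pass), so it is constant
across the band and the imaginary cross-spectrum has an analytic target.

Two cohort modes are provided:

* ``sensor`` - sources are mixed to sensors through toy lead fields and
  white sensor noise is added; exercises the beamformer and connectivity
  stages end to end (slow, for small problems).
* ``adjacency`` - subject connectivity matrices are the deterministic
  expected dwPLI of the subject's coupling configuration plus a
  subject-level Gaussian perturbation; fast, for the statistics,
  classifier and NBS stages.

Group structure mirrors an unbalanced three-group clinical design
(22 healthy controls, 25 left-hemisphere patients, 16 right-hemisphere
patients by default) with the patient contrast implanted as a
right-intra-hemispheric theta-band coupling increase.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import integrate, special

from .atlas import N_NODES, N_PER_HEMISPHERE
from .bands import DEFAULT_BANDS, BandSpec, get_band
from .beamformer import SensorTrialSet, VirtualElectrodeSet

GROUP_LABELS = ("HC", "LP", "RP")


@dataclass(frozen=True)
class CouplingSpec:
    """Phase-lag coupling on one edge: node ids are 1-based, i != j."""

    edge: tuple[int, int]
    band: str = "theta"
    coupling: float = 0.5
    phase_lag: float = math.pi / 2

    def __post_init__(self) -> None:
        i, j = self.edge
        if i == j:
            raise ValueError("coupling edge must join two distinct nodes")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if not -math.pi < self.phase_lag <= math.pi:
            raise ValueError("phase_lag must lie in (-pi, pi]")


@dataclass(frozen=True)
class SimulationConfig:
    """Source-level simulation settings for one subject."""

    fs: float = 678.17
    n_trials_3s: int = 40
    trial_length: float = 3.0
    n_rois: int = 10
    couplings: tuple[CouplingSpec, ...] = ()
    source_noise_sd: float = 0.1
    sensor_snr_db: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        f_max = max(b.f_high for b in DEFAULT_BANDS.values())
        if self.fs < 2 * f_max:
            raise ValueError(f"fs must be at least {2 * f_max} Hz")
        if self.n_trials_3s < 16:
            raise ValueError("need at least 16 trials")


@dataclass(frozen=True)
class CohortSpec:
    """Three-group cohort with implanted group effects.

    ``effect_edges`` maps a group label to coupling *deltas*: for that
    group, each listed edge's coupling is raised by ``spec.coupling``
    (clipped to [0, 1]) relative to its base value.  Edges not named in
    ``base_couplings`` start from ``background_coupling``, a diffuse
    coupling floor applied to every edge so that adjacency values sit
    away from the [0, 1] clip boundaries.
    """

    groups: tuple[tuple[str, int], ...] = (("HC", 22), ("LP", 25), ("RP", 16))
    base_couplings: tuple[CouplingSpec, ...] = ()
    effect_edges: dict[str, tuple[CouplingSpec, ...]] = field(default_factory=dict)
    between_subject_sd: float = 0.05
    mode: str = "adjacency"
    seed: int = 0
    n_rois: int = N_NODES
    bands: tuple[str, ...] = ("theta",)
    background_coupling: float = 0.08
    background_phase: float = math.pi / 2

    def __post_init__(self) -> None:
        for label, n in self.groups:
            if n < 2:
                raise ValueError(f"group {label} needs at least 2 subjects")
        if self.mode not in ("sensor", "adjacency"):
            raise ValueError("mode must be 'sensor' or 'adjacency'")


@dataclass
class Subject:
    subject_id: str
    group: str
    matrices: dict[str, np.ndarray] | None = None  # band -> n x n adjacency
    sensors: SensorTrialSet | None = None


@dataclass
class Cohort:
    subjects: list[Subject]
    spec: CohortSpec

    def by_group(self, label: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == label]

    def matrices(self, label: str, band: str) -> list[np.ndarray]:
        return [s.matrices[band] for s in self.by_group(label)]

    def save(self, outdir: str | Path) -> dict:
        """Write one directory per subject (TSV per band) plus a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict = {
            "seed": self.spec.seed,
            "mode": self.spec.mode,
            "groups": {lab: n for lab, n in self.spec.groups},
            "bands": list(self.spec.bands),
            "n_rois": self.spec.n_rois,
            "subjects": [],
        }
        for s in self.subjects:
            sdir = outdir / s.subject_id
            sdir.mkdir(exist_ok=True)
            files = []
            if s.matrices is not None:
                for band, m in s.matrices.items():
                    p = sdir / f"{s.subject_id}_{band}.tsv"
                    np.savetxt(p, m, delimiter="\t", fmt="%.8g")
                    files.append(p.name)
            if s.sensors is not None:
                p = sdir / f"{s.subject_id}_sensors.h5"
                s.sensors.save(p)
                files.append(p.name)
            manifest["subjects"].append(
                {"id": s.subject_id, "group": s.group, "files": files}
            )
        with open(outdir / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2)
        return manifest

    @classmethod
    def load(cls, outdir: str | Path) -> "Cohort":
        outdir = Path(outdir)
        with open(outdir / "manifest.json") as f:
            manifest = json.load(f)
        subjects = []
        for rec in manifest["subjects"]:
            mats = {}
            sensors = None
            for fname in rec["files"]:
                if fname.endswith(".tsv"):
                    # strip the leading "<subject_id>_" to recover the band name
                    band = fname[len(rec["id"]) + 1 : -len(".tsv")]
                    mats[band] = np.loadtxt(outdir / rec["id"] / fname, delimiter="\t")
                elif fname.endswith("_sensors.h5"):
                    sensors = SensorTrialSet.load(outdir / rec["id"] / fname)
            subjects.append(Subject(rec["id"], rec["group"], mats or None, sensors))
        spec = CohortSpec(
            groups=tuple((lab, n) for lab, n in manifest["groups"].items()),
            seed=manifest["seed"],
            mode=manifest["mode"],
            bands=tuple(manifest["bands"]),
            n_rois=manifest.get("n_rois", N_NODES),
        )
        return cls(subjects, spec)


# ---------------------------------------------------------------------------
# expected dwPLI of the coupling model

def _abs_normal_mean(mu: float, sigma: float) -> float:
    """E|N(mu, sigma^2)| for mu >= 0."""
    if sigma == 0.0:
        return mu
    z = mu / sigma
    return sigma * math.sqrt(2.0 / math.pi) * math.exp(-0.5 * z * z) + mu * special.erf(
        z / math.sqrt(2.0)
    )


@lru_cache(maxsize=4096)
def expected_dwpli(coupling: float, phase_lag: float) -> float:
    """Asymptotic dwPLI of the shared-carrier coupling model.

    At a band bin the two spectra are ``X_i = A`` and
    ``X_j = sqrt(c) A e^{-i phi} + sqrt(1-c) B`` with A, B independent
    standard complex Gaussians.  Then ``Im s = sqrt(c) sin(phi) |A|^2 +
    sqrt((1-c)/2) |A| Z`` with Z standard normal, so the large-sample
    wPLI is ``sqrt(c)|sin(phi)| / E|Im s|`` (E|A|^2 = 1) and the dwPLI
    converges to wPLI squared.  ``E|Im s|`` is computed by integrating
    the folded-normal mean over ``|A|^2 ~ Exp(1)``.
    """
    c = float(coupling)
    s_phi = abs(math.sin(phase_lag))
    if c <= 0.0 or s_phi == 0.0:
        return 0.0
    if c >= 1.0:
        return 1.0
    mu_c = math.sqrt(c) * s_phi
    sig_c = math.sqrt((1.0 - c) / 2.0)

    def integrand(u: float) -> float:
        return math.exp(-u) * _abs_normal_mean(mu_c * u, sig_c * math.sqrt(u))

    e_abs, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    wpli = mu_c / e_abs
    return float(min(wpli * wpli, 1.0))


# ---------------------------------------------------------------------------
# toy lead fields and forward projection

def sensor_array(n_sensors: int, radius: float = 1.2) -> np.ndarray:
    """Fibonacci lattice of sensor positions on a sphere around the head."""
    k = np.arange(n_sensors, dtype=float)
    golden = (1.0 + 5.0**0.5) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n_sensors
    theta = 2.0 * math.pi * k / golden
    r_xy = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z], axis=1)
    return radius * pts


def make_toy_leadfields(
    n_sensors: int,
    source_positions: np.ndarray,
    seed: int = 0,
    sensor_positions: np.ndarray | None = None,
) -> list:
    """Toy dipolar lead fields: one M x 3 matrix per source.

    The gain of orientation axis ``e_k`` at sensor m is the projection of
    the cross product ``e_k x (s_m - r)`` (the field of a current dipole in
    a homogeneous medium, up to constants) onto the sensor's pickup
    orientation, decaying with the cube of the sensor-source distance.
    Pickup orientations are radial with a small deterministic random
    tangential tilt so that all three orientation columns are excited for
    any source position.
    """
    from .beamformer import LeadField

    if n_sensors < 10:
        raise ValueError("need at least 10 sensors")
    src = np.atleast_2d(np.asarray(source_positions, dtype=float))
    if np.any(np.linalg.norm(src, axis=1) >= 1.0):
        raise ValueError("sources must lie inside the unit sphere")
    if sensor_positions is None:
        sensors = sensor_array(n_sensors)
    else:
        sensors = np.asarray(sensor_positions, dtype=float)
    # duplicate sensors make the geometry rank deficient
    d2 = np.linalg.norm(sensors[:, None] - sensors[None, :], axis=-1)
    if np.any(d2[np.triu_indices(len(sensors), 1)] < 1e-9):
        raise ValueError("duplicate sensor positions")
    rng = np.random.default_rng(seed)
    radial = sensors / np.linalg.norm(sensors, axis=1, keepdims=True)
    tilt = rng.normal(0.0, 0.25, size=sensors.shape)
    tilt -= (np.sum(tilt * radial, axis=1, keepdims=True)) * radial
    pickup = radial + tilt
    pickup /= np.linalg.norm(pickup, axis=1, keepdims=True)

    axes = np.eye(3)
    out = []
    for sid, r in enumerate(src):
        diff = sensors - r  # M x 3
        dist = np.linalg.norm(diff, axis=1)
        lf = np.empty((len(sensors), 3))
        for k in range(3):
            cross = np.cross(np.broadcast_to(axes[k], diff.shape), diff)
            lf[:, k] = np.einsum("mi,mi->m", cross, pickup) / dist**3
        if np.linalg.matrix_rank(lf) < 3:
            raise ValueError(f"lead field for source {sid} is rank deficient")
        out.append(LeadField(lf, source_id=sid + 1))
    return out


def simulate_sources(config: SimulationConfig) -> VirtualElectrodeSet:
    """Simulate ROI source trials with the configured phase-lag couplings."""
    seen: set[tuple[int, str]] = set()
    for cs in config.couplings:
        key = (cs.edge[1], cs.band)
        if key in seen:
            raise ValueError(
                f"node {cs.edge[1]} is the target of two couplings in band {cs.band}"
            )
        seen.add(key)
    rng = np.random.default_rng(config.seed)
    n = int(round(config.trial_length * config.fs))
    n_t = config.n_trials_3s
    data = rng.normal(0.0, config.source_noise_sd, (config.n_rois, n_t, n))

    freqs = np.fft.rfftfreq(n, 1.0 / config.fs)
    bands = {cs.band for cs in config.couplings}
    for band_name in sorted(bands):
        band = get_band(band_name)
        mask = (freqs >= band.f_low) & (freqs <= band.f_high)
        m = int(mask.sum())
        if m == 0:
            raise ValueError(f"band {band_name} has no bins at this trial length")
        scale = n / math.sqrt(2.0 * m)  # unit time-domain variance
        band_cs = [cs for cs in config.couplings if cs.band == band_name]
        src_ids = sorted({cs.edge[0] for cs in band_cs})
        spectra: dict[int, np.ndarray] = {}
        for i in src_ids:
            z = (
                rng.normal(size=(n_t, m)) + 1j * rng.normal(size=(n_t, m))
            ) / math.sqrt(2.0)
            spectra[i] = z
            full = np.zeros((n_t, len(freqs)), dtype=complex)
            full[:, mask] = z
            data[i - 1] += scale * np.fft.irfft(full, n=n, axis=-1)
        for cs in band_cs:
            i, j = cs.edge
            zi = spectra[i]
            z_ind = (
                rng.normal(size=(n_t, m)) + 1j * rng.normal(size=(n_t, m))
            ) / math.sqrt(2.0)
            zj = (
                math.sqrt(cs.coupling) * zi * np.exp(-1j * cs.phase_lag)
                + math.sqrt(1.0 - cs.coupling) * z_ind
            )
            full = np.zeros((n_t, len(freqs)), dtype=complex)
            full[:, mask] = zj
            data[j - 1] += scale * np.fft.irfft(full, n=n, axis=-1)
    return VirtualElectrodeSet(data, config.fs)


def project_to_sensors(
    sources: VirtualElectrodeSet,
    leadfields: list,
    orientations: np.ndarray,
    sensor_snr_db: float | None = 20.0,
    seed: int = 0,
) -> SensorTrialSet:
    """Mix sources to sensors: B = sum_s (L_s @ eta_s) v_s(t) + white noise."""
    orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
    if len(leadfields) != sources.n_rois or len(orientations) != sources.n_rois:
        raise ValueError("need one lead field and one orientation per source")
    gains = np.stack(
        [lf.matrix @ (eta / np.linalg.norm(eta)) for lf, eta in zip(leadfields, orientations)],
        axis=1,
    )  # M x R
    # R x trials x samples -> trials x M x samples
    sig = np.einsum("mr,rts->tms", gains, sources.data)
    if sensor_snr_db is not None:
        p_sig = float(np.mean(sig**2))
        sd = math.sqrt(p_sig / (10.0 ** (sensor_snr_db / 10.0))) if p_sig > 0 else 0.0
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, sd, sig.shape)
    return SensorTrialSet(sig, sources.fs, sources.trial_indices)


# ---------------------------------------------------------------------------
# cohorts

def sensor_geometry(
    seed: int, n_rois: int, n_sensors: int = 60
) -> tuple[np.ndarray, list, np.ndarray]:
    """Deterministic forward model shared by all subjects of a cohort.

    Returns (source positions, toy lead fields, source orientations); a
    pure function of the seed, so the beamforming stage can rebuild the
    same geometry from the cohort manifest.
    """
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-0.55, 0.55, (n_rois, 3))
    lfs = make_toy_leadfields(n_sensors, pos, seed=seed)
    orient = rng.normal(size=(n_rois, 3))
    orient /= np.linalg.norm(orient, axis=1, keepdims=True)
    return pos, lfs, orient

def _expected_adjacency(
    spec: CohortSpec, group: str
) -> dict[str, np.ndarray]:
    """Deterministic expected-dwPLI adjacency per band for one group."""
    n = spec.n_rois
    bands = set(spec.bands)
    bands |= {cs.band for cs in spec.base_couplings}
    for deltas in spec.effect_edges.values():
        bands |= {cs.band for cs in deltas}
    bg = expected_dwpli(spec.background_coupling, spec.background_phase)
    out = {}
    for band in sorted(bands):
        m = np.full((n, n), bg, dtype=float)
        np.fill_diagonal(m, 0.0)
        base_c: dict[tuple[int, int], tuple[float, float]] = {}
        for cs in spec.base_couplings:
            if cs.band != band:
                continue
            e = tuple(sorted(cs.edge))
            base_c[e] = (cs.coupling, cs.phase_lag)
            v = expected_dwpli(cs.coupling, cs.phase_lag)
            m[e[0] - 1, e[1] - 1] = m[e[1] - 1, e[0] - 1] = v
        for cs in spec.effect_edges.get(group, ()):
            if cs.band != band:
                continue
            e = tuple(sorted(cs.edge))
            c0, phi = base_c.get(
                e, (spec.background_coupling, spec.background_phase)
            )
            c_eff = float(np.clip(c0 + cs.coupling, 0.0, 1.0))
            v = expected_dwpli(c_eff, phi)
            m[e[0] - 1, e[1] - 1] = m[e[1] - 1, e[0] - 1] = v
        out[band] = m
    return out


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort; a pure function of the spec (incl. its seed)."""
    root = np.random.default_rng(spec.seed)
    subjects: list[Subject] = []
    if spec.mode == "adjacency":
        n = spec.n_rois
        iu = np.triu_indices(n, 1)
        for label, n_sub in spec.groups:
            expected = _expected_adjacency(spec, label)
            for k in range(n_sub):
                mats = {}
                for band, e_mat in expected.items():
                    noise = root.normal(0.0, spec.between_subject_sd, len(iu[0]))
                    m = e_mat.copy()
                    m[iu] += noise
                    m.T[iu] = m[iu]
                    np.clip(m, 0.0, 1.0, out=m)
                    np.fill_diagonal(m, 0.0)
                    mats[band] = m
                subjects.append(Subject(f"{label}{k + 1:03d}", label, mats))
    else:
        for label, n_sub in spec.groups:
            deltas = {
                tuple(sorted(cs.edge)): cs for cs in spec.effect_edges.get(label, ())
            }
            for k in range(n_sub):
                couplings = []
                for cs in spec.base_couplings:
                    e = tuple(sorted(cs.edge))
                    c = cs.coupling + (deltas[e].coupling if e in deltas else 0.0)
                    c = float(
                        np.clip(
                            c + root.normal(0.0, spec.between_subject_sd), 0.0, 1.0
                        )
                    )
                    couplings.append(replace(cs, coupling=c))
                sub_seed = int(root.integers(0, 2**31 - 2))
                cfg = SimulationConfig(
                    n_rois=spec.n_rois,
                    couplings=tuple(couplings),
                    seed=sub_seed,
                )
                sources = simulate_sources(cfg)
                _, lfs, orient = sensor_geometry(spec.seed, spec.n_rois)
                sensors = project_to_sensors(
                    sources, lfs, orient, sensor_snr_db=20.0, seed=sub_seed + 1
                )
                subjects.append(Subject(f"{label}{k + 1:03d}", label, None, sensors))
    return Cohort(subjects, spec)


def right_block_edges(n_edges: int | None = None) -> list[tuple[int, int]]:
    """Edges inside the right hemispheric block (node ids 124-246).

    With ``n_edges`` given, returns that many edges among the lowest-id
    right-hemisphere nodes (a near-clique, hence connected); otherwise all
    right-right edges.
    """
    lo, hi = N_PER_HEMISPHERE + 1, 2 * N_PER_HEMISPHERE
    if n_edges is None:
        return [(i, j) for i in range(lo, hi + 1) for j in range(i + 1, hi + 1)]
    edges = []
    for i in range(lo, hi + 1):
        for j in range(i + 1, hi + 1):
            edges.append((i, j))
            if len(edges) == n_edges:
                return edges
    raise ValueError("too many edges requested")


def right_clique_edges(n_nodes: int = 25) -> list[tuple[int, int]]:
    """All edges of the clique over the first ``n_nodes`` right-block nodes."""
    lo = N_PER_HEMISPHERE + 1
    if not 2 <= n_nodes <= N_PER_HEMISPHERE:
        raise ValueError(f"n_nodes must lie in [2, {N_PER_HEMISPHERE}]")
    nodes = range(lo, lo + n_nodes)
    return [(i, j) for i in nodes for j in nodes if i < j]


def default_cohort_spec(
    seed: int = 0,
    delta: float = 0.10,
    n_effect_nodes: int = 25,
    groups: tuple[tuple[str, int], ...] = (("HC", 22), ("LP", 25), ("RP", 16)),
    bands: tuple[str, ...] = tuple(DEFAULT_BANDS),
) -> CohortSpec:
    """Default adjacency-mode cohort with a focal right-theta RP effect.

    The RP group's theta coupling is raised by ``delta`` on every edge of
    a designated right-hemisphere subnetwork -- the clique over the first
    ``n_effect_nodes`` right-block nodes -- emulating elevated right
    intra-hemispheric theta connectivity in right-lateralized patients.

    The effect is focal rather than a uniform shift of the whole right
    block: the Onnela clustering/transitivity measures normalize weights
    by the quadrant maximum, so a uniform shift leaves them essentially
    unchanged, whereas a boosted clique raises triangle weights relative
    to the rest of the graph and moves efficiency, path length and
    transitivity together.
    """
    effect = tuple(
        CouplingSpec(edge=e, band="theta", coupling=delta)
        for e in right_clique_edges(n_effect_nodes)
    )
    return CohortSpec(
        groups=groups,
        effect_edges={"RP": effect},
        seed=seed,
        bands=bands,
    )


def nbs_recovery_spec(
    seed: int = 0,
    n_edges: int = 20,
    delta: float = 0.3,
    n_per_group: int = 15,
) -> tuple[CohortSpec, list[tuple[int, int]]]:
    """Two-group cohort with a focal right-theta effect for NBS recovery.

    Returns the spec and the list of implanted edges.
    """
    edges = right_block_edges(n_edges)
    effect = tuple(
        CouplingSpec(edge=e, band="theta", coupling=delta) for e in edges
    )
    spec = CohortSpec(
        groups=(("LP", n_per_group), ("RP", n_per_group)),
        effect_edges={"RP": effect},
        seed=seed,
        bands=("theta",),
    )
    return spec, edges


def sensor_cohort_spec(
    seed: int = 0,
    groups: tuple[tuple[str, int], ...] = (("LP", 2), ("RP", 2)),
    n_rois: int = 8,
) -> CohortSpec:
    """Small sensor-mode cohort exercising the full reconstruction path.

    Two theta couplings are implanted ((1,2) and (3,4)); the RP group's
    (1,2) coupling is raised, mirroring the adjacency-mode group contrast
    at a scale where beamforming every subject stays cheap.
    """
    base = (
        CouplingSpec((1, 2), "theta", 0.4, math.pi / 2),
        CouplingSpec((3, 4), "theta", 0.4, math.pi / 2),
    )
    effect = {"RP": (CouplingSpec((1, 2), "theta", 0.3, math.pi / 2),)}
    return CohortSpec(
        groups=groups,
        base_couplings=base,
        effect_edges=effect,
        mode="sensor",
        seed=seed,
        n_rois=n_rois,
        bands=("theta",),
    )


def null_cohort_spec(
    seed: int = 0,
    n_per_group: int = 15,
    bands: tuple[str, ...] = ("theta",),
) -> CohortSpec:
    """Two-group cohort with no implanted effect (all deltas zero)."""
    return CohortSpec(
        groups=(("LP", n_per_group), ("RP", n_per_group)),
        seed=seed,
        bands=bands,
    )
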
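"""Synthetic multi-site, two-session, three-group resting-state cohorts.

The generator emulates the statistical structure a pre/post-task amygdala
connectivity analysis assumes: a latent AR(1) seed signal per subject-session,
seed-sphere voxels carrying that signal, named network voxel sets coupled to
it with group-by-session weights, AR(1) background noise, optional spatial
smoothing, per-site intensity offsets/gains, and clinical scores linked to
each subject's true connectivity change.  Ground truth (true couplings,
effect masks, generating slopes) is returned alongside so recovery can be
tested.

Generative model per subject-session, with latent seed signal s(t) and
i.i.d. AR(1) noise fields eps:

* seed voxels:        s + seed_noise_sd * eps
* network voxels:     w*s + sqrt(1 - w^2) * eps   (w in [0, 1))
* background voxels:  eps

so that every non-seed voxel has marginal variance noise_sd^2 regardless of
w, and the population voxel-seed correlation in a network is w.  Coupling
weights are jittered per subject-session on the atanh scale, which gives
subjects a well-defined true Fisher-z change for clinical scores to track.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, signal

from .seed import SeedSpec, build_sphere_mask
from .volume_io import Bold4D, BrainMask, ImageGrid, write_volume

__all__ = [
    "NetworkSpec",
    "ClinicalLink",
    "SimConfig",
    "GroundTruth",
    "CohortManifest",
    "ball_network",
    "default_config",
    "simulate_cohort",
    "plant_interaction",
    "clinical_noise_sd_for_target_r",
    "ar1_noise",
]

SESSIONS = ("pre", "post")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Group-wise score distributions used for the unlinked clinical covariates
#: (means/SDs of the three study groups' clinical instruments).
SCORE_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "bsi": {"BPD": (1.68, 0.55), "NPC": (0.13, 0.13), "CPD": (1.11, 0.43)},
    "bpd_checklist": {"BPD": (118.44, 25.58), "NPC": (50.68, 5.21), "CPD": (74.80, 17.31)},
    "itec_sexual_abuse": {"BPD": (9.44, 8.85), "NPC": (0.13, 0.42), "CPD": (2.26, 5.43)},
    "itec_physical_abuse": {"BPD": (17.15, 12.40), "NPC": (1.69, 3.61), "CPD": (7.00, 10.95)},
    "itec_emotional_abuse": {"BPD": (20.35, 8.93), "NPC": (2.47, 3.32), "CPD": (13.06, 8.49)},
    "itec_emotional_neglect": {"BPD": (11.28, 6.99), "NPC": (0.82, 2.07), "CPD": (6.14, 6.55)},
    "itec_physical_neglect": {"BPD": (10.68, 9.42), "NPC": (0.88, 2.82), "CPD": (4.35, 6.90)},
    "dissociation_pre": {"BPD": (19.81, 19.41), "NPC": (5.18, 6.60), "CPD": (6.37, 6.98)},
    "dissociation_post": {"BPD": (31.87, 26.85), "NPC": (6.40, 7.81), "CPD": (15.36, 20.60)},
}

ITEC_SUBSCALES = [k for k in SCORE_DISTRIBUTIONS if k.startswith("itec_")]


@dataclass(frozen=True)
class NetworkSpec:
    """A named voxel set with per-(group, session) seed-coupling weights."""

    name: str
    voxel_indices: tuple[tuple[int, int, int], ...]
    coupling: dict  # {(group, session): w}

    def __post_init__(self) -> None:
        for key, w in self.coupling.items():
            if not 0 <= w < 1:
                raise ValueError(f"coupling weight {w} for {key} must satisfy w^2 < 1")

    def mask(self, grid: ImageGrid) -> BrainMask:
        arr = np.zeros(grid.dims, dtype=bool)
        idx = np.asarray(self.voxel_indices)
        arr[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return BrainMask(grid, arr)

    def weight(self, group: str, session: str) -> float:
        return float(self.coupling.get((group, session), 0.0))


@dataclass(frozen=True)
class ClinicalLink:
    """score = slope * (true network Delta-z) + Gaussian noise."""

    score: str
    network: str
    slope: float
    noise_sd: float
    base_mean: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    dims: tuple[int, int, int] = (24, 24, 16)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 180
    tr_seconds: float = 2.0
    groups: tuple[tuple[str, int], ...] = (("BPD", 48), ("NPC", 39), ("CPD", 21))
    n_sites: int = 3
    seed_centers_mm: tuple = ((-22.0, -6.0, -14.0), (22.0, -6.0, -14.0))
    seed_radius_mm: float = 5.0
    networks: tuple[NetworkSpec, ...] = ()
    noise_sd: float = 1.0
    seed_noise_sd: float = 0.3
    ar1_coef: float = 0.3
    spatial_fwhm_mm: float = 6.0
    coupling_jitter_sd: float = 0.15
    site_offset_sd: float = 5.0
    site_gain_sd: float = 0.0
    baseline: float = 100.0
    clinical_links: tuple[ClinicalLink, ...] = ()
    medicated_prop: float = 31 / 48
    allow_seed_overlap: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for _, n in self.groups):
            raise ValueError("every group needs at least 2 subjects")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        if not -1 <= self.ar1_coef <= 1:
            raise ValueError("ar1_coef must lie in [-1, 1]")
        grid = self.grid
        seed = self.seed_union(grid)
        for net in self.networks:
            netmask = net.mask(grid)
            if not self.allow_seed_overlap and (netmask.included & seed.included).any():
                raise ValueError(
                    f"network {net.name!r} overlaps the seed spheres; "
                    "set allow_seed_overlap=True to permit this"
                )

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid.standard(self.dims, self.voxel_size_mm)

    @property
    def seed_spec(self) -> SeedSpec:
        return SeedSpec(
            left_mm=tuple(self.seed_centers_mm[0]),
            right_mm=tuple(self.seed_centers_mm[1]),
            radius_mm=self.seed_radius_mm,
        )

    def seed_union(self, grid: ImageGrid | None = None) -> BrainMask:
        grid = grid or self.grid
        left, right = self.seed_spec.masks(grid)
        return BrainMask(grid, left.included | right.included)

    def network(self, name: str) -> NetworkSpec:
        for net in self.networks:
            if net.name == name:
                return net
        raise KeyError(f"no network named {name!r}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        nets = []
        grid = ImageGrid.standard(
            tuple(raw.get("dims", cls.dims)), raw.get("voxel_size_mm", cls.voxel_size_mm)
        )
        for spec in raw.pop("networks", []):
            coupling = {
                (group, ses): float(w)
                for group, sessions in spec["coupling"].items()
                for ses, w in sessions.items()
            }
            nets.append(
                ball_network(
                    grid, spec["center_mm"], spec["n_voxels"], spec["name"], coupling
                )
            )
        links = [ClinicalLink(**d) for d in raw.pop("clinical_links", [])]
        raw["groups"] = tuple((g, int(n)) for g, n in raw.get("groups", cls.groups))
        raw.pop("dims", None)
        dims = tuple(grid.dims)
        return cls(dims=dims, networks=tuple(nets), clinical_links=tuple(links), **raw)


def ball_network(
    grid: ImageGrid, center_mm, n_voxels: int, name: str, coupling: dict
) -> NetworkSpec:
    """The ``n_voxels`` grid voxels nearest to ``center_mm`` (compact blob)."""
    centers = grid.voxel_centers_mm().reshape(-1, 3)
    d2 = ((centers - np.asarray(center_mm, float)) ** 2).sum(axis=1)
    idx = np.indices(grid.dims).reshape(3, -1).T
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))
    chosen = idx[order[:n_voxels]]
    return NetworkSpec(name, tuple(map(tuple, chosen.tolist())), dict(coupling))


def clinical_noise_sd_for_target_r(
    target_r: float,
    slope: float,
    jitter_sd: float,
    n_timepoints: int = 180,
) -> float:
    """Score-noise SD giving a desired population score-vs-measured-Delta-z r.

    The subject's true Delta-z varies with variance 2*jitter_sd^2 (independent
    pre/post jitter on the atanh scale); a single voxel's measured Delta-z adds
    Fisher-z sampling variance 2/(T-3).  Solving the attenuation identity for
    the score noise yields the returned SD.
    """
    if not 0 < target_r < 1:
        raise ValueError("target_r must lie in (0, 1)")
    var_t = 2.0 * jitter_sd**2
    if var_t == 0:
        raise ValueError("a nonzero coupling jitter is required for a finite slope")
    var_v = var_t + 2.0 / (n_timepoints - 3)
    var_score_needed = slope**2 * var_t**2 / (target_r**2 * var_v)
    var_noise = var_score_needed - slope**2 * var_t
    if var_noise <= 0:
        raise ValueError(f"target r={target_r} is unattainable at this jitter")
    return float(np.sqrt(var_noise))


def default_config(**overrides) -> SimConfig:
    """Study-sized default: 48/39/21 subjects, 3 sites, one planted network.

    The planted "mpfc" network couples to the seed at w=0.1 in every group
    before the task and rises to w=0.5 after the task in NPC only, mirroring
    a healthy-control-specific post-task connectivity increase; BPDSI tracks
    the true network Delta-z at a population correlation of 0.45.
    """
    cfg_kwargs = dict(overrides)
    dims = cfg_kwargs.get("dims", SimConfig.dims)
    voxel = cfg_kwargs.get("voxel_size_mm", SimConfig.voxel_size_mm)
    grid = ImageGrid.standard(tuple(dims), voxel)
    if "networks" not in cfg_kwargs:
        coupling = {
            ("NPC", "pre"): 0.1,
            ("NPC", "post"): 0.5,
            ("BPD", "pre"): 0.1,
            ("BPD", "post"): 0.1,
            ("CPD", "pre"): 0.1,
            ("CPD", "post"): 0.1,
        }
        cfg_kwargs["networks"] = (ball_network(grid, (-4.0, 30.0, 3.0), 40, "mpfc", coupling),)
    if "clinical_links" not in cfg_kwargs:
        jitter = cfg_kwargs.get("coupling_jitter_sd", SimConfig.coupling_jitter_sd)
        T = cfg_kwargs.get("n_timepoints", SimConfig.n_timepoints)
        noise = clinical_noise_sd_for_target_r(0.45, slope=20.0, jitter_sd=jitter, n_timepoints=T)
        cfg_kwargs["clinical_links"] = (
            ClinicalLink("bpdsi", "mpfc", slope=20.0, noise_sd=noise, base_mean=30.0),
        )
    return SimConfig(**cfg_kwargs)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    config: SimConfig
    network_masks: dict  # name -> 3D bool array
    coupling: dict  # name -> {(group, session): w}
    eta: pd.DataFrame  # per subject x session x network atanh-scale jitter
    true_delta_z: pd.DataFrame  # per subject x network true z change
    site_offsets: np.ndarray
    site_gains: np.ndarray
    clinical_links: tuple[ClinicalLink, ...]

    def true_interaction(self, network: str, group_a: str, group_b: str) -> float:
        """[dz(post)-dz(pre)]_A - [dz(post)-dz(pre)]_B on the atanh scale."""
        w = self.coupling[network]
        da = np.arctanh(w.get((group_a, "post"), 0.0)) - np.arctanh(w.get((group_a, "pre"), 0.0))
        db = np.arctanh(w.get((group_b, "post"), 0.0)) - np.arctanh(w.get((group_b, "pre"), 0.0))
        return float(da - db)

    def to_json(self, path) -> None:
        payload = {
            "coupling": {
                name: {f"{g}/{s}": w for (g, s), w in cw.items()}
                for name, cw in self.coupling.items()
            },
            "network_voxels": {
                name: np.argwhere(mask).tolist() for name, mask in self.network_masks.items()
            },
            "site_offsets": self.site_offsets.tolist(),
            "site_gains": self.site_gains.tolist(),
            "clinical_links": [
                {
                    "score": l.score,
                    "network": l.network,
                    "slope": l.slope,
                    "noise_sd": l.noise_sd,
                }
                for l in self.clinical_links
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


class CohortManifest:
    """Subject x session registry with lazily generated (or on-disk) volumes."""

    def __init__(
        self,
        sessions: pd.DataFrame,
        clinical: pd.DataFrame,
        config: SimConfig,
        truth: GroundTruth | None = None,
    ):
        self.sessions = sessions.reset_index(drop=True)
        self.clinical = clinical.reset_index(drop=True)
        self.config = config
        self._truth = truth

    def __len__(self) -> int:
        return len(self.sessions)

    @property
    def subjects(self) -> pd.DataFrame:
        cols = ["subject_id", "group", "site", "medicated"]
        return self.sessions[cols].drop_duplicates().reset_index(drop=True)

    def load_bold(self, subject_id: str, session: str) -> Bold4D:
        row = self.sessions[
            (self.sessions.subject_id == subject_id) & (self.sessions.session == session)
        ]
        if row.empty:
            raise KeyError(f"no session {session!r} for subject {subject_id!r}")
        row = row.iloc[0]
        if isinstance(row.path, str) and row.path:
            from .volume_io import read_volume

            return read_volume(row.path, tr_seconds=self.config.tr_seconds)
        if self._truth is None:
            raise ValueError("manifest has neither file paths nor generator truth")
        data = _generate_bold(self.config, self._truth, row)
        return Bold4D(self.config.grid, data, tr_seconds=self.config.tr_seconds)

    def write(self, out_dir) -> "CohortManifest":
        """Materialize all volumes plus manifest/clinical/ground-truth files."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for _, row in self.sessions.iterrows():
            bold = self.load_bold(row.subject_id, row.session)
            p = out_dir / f"{row.subject_id}_ses-{row.session}_bold.nii.gz"
            write_volume(p, bold)
            paths.append(str(p))
        sessions = self.sessions.assign(path=paths)
        sessions.to_csv(out_dir / "manifest.csv", index=False)
        self.clinical.to_csv(out_dir / "clinical.csv", index=False)
        if self._truth is not None:
            self._truth.to_json(out_dir / "ground_truth.json")
        return CohortManifest(sessions, self.clinical, self.config, self._truth)


def ar1_noise(rng: np.random.Generator, shape, phi: float, dtype=np.float32) -> np.ndarray:
    """Stationary unit-variance AR(1) noise along the last axis."""
    e = rng.standard_normal(shape, dtype=dtype)
    if phi == 0:
        return e
    u = e * np.sqrt(1.0 - phi**2, dtype=dtype)
    u[..., 0] = e[..., 0]  # stationary start: x_0 ~ N(0, 1)
    return signal.lfilter([1.0], [1.0, -phi], u, axis=-1).astype(dtype)


def _generate_bold(config: SimConfig, truth: GroundTruth, row) -> np.ndarray:
    """One subject-session volume, bitwise-reproducible from its rng key."""
    rng = np.random.default_rng(int(row.rng_key))
    T, phi = config.n_timepoints, config.ar1_coef
    s = ar1_noise(rng, (T,), phi)
    eps = ar1_noise(rng, (*config.dims, T), phi)
    data = eps
    grid = config.grid
    for net in config.networks:
        w = net.weight(row.group, row.session)
        if w == 0:
            continue
        eta = truth.eta.loc[
            (truth.eta.subject_id == row.subject_id)
            & (truth.eta.session == row.session)
            & (truth.eta.network == net.name),
            "eta",
        ].iloc[0]
        w_eff = np.tanh(np.arctanh(w) + eta)
        m = truth.network_masks[net.name]
        data[m] = np.float32(w_eff) * s[np.newaxis, :] + np.float32(
            np.sqrt(1.0 - w_eff**2)
        ) * eps[m]
    seed = config.seed_union(grid).included
    data[seed] = s[np.newaxis, :] + np.float32(config.seed_noise_sd) * eps[seed]
    data *= np.float32(config.noise_sd)
    if config.spatial_fwhm_mm > 0:
        sig = config.spatial_fwhm_mm * _FWHM_TO_SIGMA / config.voxel_size_mm
        data = ndimage.gaussian_filter(data, sigma=(sig, sig, sig, 0.0))
    gain = truth.site_gains[int(row.site)]
    offset = truth.site_offsets[int(row.site)]
    data += np.float32(config.baseline * gain + offset)
    return data


def simulate_cohort(
    config: SimConfig, out_dir=None
) -> tuple[CohortManifest, GroundTruth]:
    """Draw a cohort; volumes are generated lazily unless ``out_dir`` is given.

    Identical (config, rng_seed) always reproduce the same manifest, clinical
    scores and voxel data bitwise.
    """
    rng = np.random.default_rng(config.rng_seed)
    grid = config.grid

    rows = []
    idx = 0
    for group, n in config.groups:
        for k in range(n):
            medicated = bool(
                group == "BPD" and rng.random() < config.medicated_prop
            )
            rows.append(
                {
                    "subject_id": f"sub-{group}{k + 1:03d}",
                    "group": group,
                    "site": idx % config.n_sites,
                    "medicated": medicated,
                }
            )
            idx += 1
    subjects = pd.DataFrame(rows)

    site_offsets = rng.normal(0.0, config.site_offset_sd, size=config.n_sites)
    site_gains = 1.0 + rng.normal(0.0, config.site_gain_sd, size=config.n_sites)

    # per subject x session x network coupling jitter (atanh scale)
    eta_rows = []
    for _, sub in subjects.iterrows():
        for ses in SESSIONS:
            for net in config.networks:
                eta_rows.append(
                    {
                        "subject_id": sub.subject_id,
                        "session": ses,
                        "network": net.name,
                        "eta": rng.normal(0.0, config.coupling_jitter_sd),
                    }
                )
    eta = pd.DataFrame(eta_rows, columns=["subject_id", "session", "network", "eta"])

    # true per-subject Delta-z per network (0 where coupling is 0 -- no jitter)
    tdz_rows = []
    for _, sub in subjects.iterrows():
        for net in config.networks:
            vals = {}
            for ses in SESSIONS:
                w = net.weight(sub.group, ses)
                if w == 0:
                    vals[ses] = 0.0
                else:
                    e = eta.loc[
                        (eta.subject_id == sub.subject_id)
                        & (eta.session == ses)
                        & (eta.network == net.name),
                        "eta",
                    ].iloc[0]
                    vals[ses] = np.arctanh(w) + e
            tdz_rows.append(
                {
                    "subject_id": sub.subject_id,
                    "network": net.name,
                    "true_delta_z": vals["post"] - vals["pre"],
                }
            )
    true_dz = pd.DataFrame(
        tdz_rows, columns=["subject_id", "network", "true_delta_z"]
    )

    clinical = subjects[["subject_id", "group"]].copy()
    linked = {l.score for l in config.clinical_links}
    for score, dists in SCORE_DISTRIBUTIONS.items():
        if score in linked:
            continue
        vals = []
        for _, sub in subjects.iterrows():
            mean, sd = dists.get(sub.group, (0.0, 1.0))
            vals.append(max(0.0, rng.normal(mean, sd)))
        clinical[score] = vals
    for link in config.clinical_links:
        dz = true_dz[true_dz.network == link.network].set_index("subject_id")[
            "true_delta_z"
        ]
        vals = [
            max(
                0.0,
                link.base_mean
                + link.slope * dz[sub]
                + rng.normal(0.0, link.noise_sd),
            )
            for sub in subjects.subject_id
        ]
        clinical[link.score] = vals
    clinical["itec_total"] = clinical[ITEC_SUBSCALES].sum(axis=1)
    clinical["dissociation_change"] = (
        clinical["dissociation_post"] - clinical["dissociation_pre"]
    )

    sess_rows = []
    for _, sub in subjects.iterrows():
        for ses in SESSIONS:
            sess_rows.append(
                {
                    **sub.to_dict(),
                    "session": ses,
                    "path": "",
                    "rng_key": int(rng.integers(2**31)),
                }
            )
    sessions = pd.DataFrame(sess_rows)

    truth = GroundTruth(
        config=config,
        network_masks={n.name: n.mask(grid).included for n in config.networks},
        coupling={n.name: dict(n.coupling) for n in config.networks},
        eta=eta,
        true_delta_z=true_dz,
        site_offsets=site_offsets,
        site_gains=site_gains,
        clinical_links=config.clinical_links,
    )
    manifest = CohortManifest(sessions, clinical, config, truth)
    if out_dir is not None:
        manifest = manifest.write(out_dir)
    return manifest, truth


def plant_interaction(
    config: SimConfig, network: str, w_by_group_session: dict
) -> SimConfig:
    """Return a config whose named network carries the given 2x2 couplings.

    ``w_by_group_session`` maps (group, session) -> w; the resulting cohort's
    true interaction effect between groups A and B is
    [atanh(w_A,post) - atanh(w_A,pre)] - [atanh(w_B,post) - atanh(w_B,pre)].
    """
    target = config.network(network)  # raises KeyError for unknown names
    coupling = dict(target.coupling)
    for (group, ses), w in w_by_group_session.items():
        coupling[(group, ses)] = float(w)
    new_net = NetworkSpec(target.name, target.voxel_indices, coupling)
    nets = tuple(new_net if n.name == network else n for n in config.networks)
    return replace(config, networks=nets)
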
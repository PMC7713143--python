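"""Synthetic micro-CT phantoms of a plated tibial osteotomy.

The phantom emulates the specimen geometry of an ovine transverse
tibial-osteotomy model: a hollow cortical shaft interrupted by a 3 mm
parallel gap, fixed with a six-hole plate (represented by its screw
positions) on the *cis* side, with periosteal callus compartments of
prescribed volume and mineral density accreted around the gap.  Every
phantom carries exact ground truth (label field, per-compartment voxel
counts and densities), so each downstream stage — segmentation, ROI
definition, morphometry, statistics — can be validated against known
answers without animal data.

Densities are calibrated mgHA/ccm values: cortical bone ~1200, callus in
the 250–1000 band, marrow ~100, background 0, metal far above bone.
Noise is additive Gaussian in density units, applied after labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import AXIAL_AXIS, CalibratedVolume

# Label codes of the truth field
LBL_BACKGROUND = 0
LBL_MARROW = 1
LBL_CORTICAL = 2
LBL_CALLUS_CIS = 3
LBL_CALLUS_TRANS = 4
LBL_METAL = 5

LABEL_NAMES = {
    LBL_BACKGROUND: "background",
    LBL_MARROW: "marrow",
    LBL_CORTICAL: "cortical",
    LBL_CALLUS_CIS: "callus_cis",
    LBL_CALLUS_TRANS: "callus_trans",
    LBL_METAL: "metal",
}

CALLUS_BAND = (250.0, 1000.0)  # mgHA/ccm


class PhantomSizingError(ValueError):
    """Requested compartment cannot be voxelized within the field of view."""


@dataclass
class CallusCompartmentSpec:
    """One periosteal callus compartment.

    side
        ``"cis"`` (plate side, positive half-space) or ``"trans"``.
    target_volume
        Requested volume in ccm (cm^3).
    density
        Mineral density in mgHA/ccm; must lie in the callus band [250, 1000].
    axial_extent
        Axial length (mm) of the compartment, centred on the gap.
    """

    side: str
    target_volume: float
    density: float
    axial_extent: float

    def __post_init__(self) -> None:
        if self.side not in ("cis", "trans"):
            raise ValueError(f"side must be 'cis' or 'trans', got {self.side!r}")
        if self.target_volume <= 0:
            raise ValueError("target_volume must be > 0")
        if not (CALLUS_BAND[0] <= self.density <= CALLUS_BAND[1]):
            raise ValueError(
                f"callus density {self.density} outside the {CALLUS_BAND} mgHA/ccm band"
            )
        if self.axial_extent <= 0:
            raise ValueError("axial_extent must be > 0")


@dataclass
class PhantomSpec:
    """Geometry, composition and acquisition parameters of one phantom.

    Lengths in mm, densities in mgHA/ccm.  The shaft axis is the third
    image axis; the cis (plate) side is the positive first axis.
    """

    shaft_outer_diameter: float = 20.0
    shaft_inner_diameter: float = 12.0
    shaft_length: float = 100.0
    gap_width: float = 3.0
    voxel_pitch: float = 0.0607
    cortical_density: float = 1200.0
    marrow_density: float = 100.0
    callus_compartments: list[CallusCompartmentSpec] = field(default_factory=list)
    screw_axial_positions: list[float] | None = None
    include_metal: bool = False
    metal_density: float = 3000.0
    screw_diameter: float = 5.0
    lateral_margin: float = 8.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.shaft_inner_diameter < self.shaft_outer_diameter:
            raise ValueError("shaft_inner_diameter must be < shaft_outer_diameter")
        if not (0 < self.gap_width < self.shaft_length):
            raise ValueError("gap_width must be positive and smaller than shaft_length")
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.screw_axial_positions is None:
            self.screw_axial_positions = self._default_screw_positions()
        centre = self.shaft_length / 2.0
        gap = (centre - self.gap_width / 2.0, centre + self.gap_width / 2.0)
        prox = [z for z in self.screw_axial_positions if z < gap[0]]
        dist = [z for z in self.screw_axial_positions if z > gap[1]]
        if len(prox) + len(dist) != len(self.screw_axial_positions):
            raise ValueError("a screw position lies inside the osteotomy gap")
        for z in self.screw_axial_positions:
            if not (0 < z < self.shaft_length):
                raise ValueError(f"screw position {z} mm outside the shaft")

    def _default_screw_positions(self) -> list[float]:
        # six-hole plate: three screws per fragment; innermost hole pair
        # straddles the gap, 13 mm hole spacing
        centre = self.shaft_length / 2.0
        offsets = (6.5, 19.5, 32.5)
        pos = [centre - o for o in offsets] + [centre + o for o in offsets]
        if min(pos) <= 0 or max(pos) >= self.shaft_length:
            # short demo shafts: compress the spacing to fit
            half = self.shaft_length / 2.0 - 2.0
            step = (half - self.gap_width / 2.0 - 2.0) / 3.0
            offsets = tuple(self.gap_width / 2.0 + 2.0 + i * step for i in range(1, 4))
            pos = [centre - o for o in offsets] + [centre + o for o in offsets]
        return sorted(pos)

    @property
    def gap_bounds(self) -> tuple[float, float]:
        centre = self.shaft_length / 2.0
        return (centre - self.gap_width / 2.0, centre + self.gap_width / 2.0)


@dataclass
class PhantomTruth:
    """Exact bookkeeping of a generated phantom."""

    label_volume: np.ndarray
    true_volumes: dict[str, float]  # compartment -> ccm
    true_densities: dict[str, float]  # compartment -> mgHA/ccm
    cis_halfspace_normal: np.ndarray  # unit vector, in-plane
    gap_bounds: tuple[float, float]  # mm along the bone axis
    screw_axial_positions: list[float]
    voxel_pitch: tuple[float, float, float]


def _grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int, int]]:
    p = spec.voxel_pitch
    fov = spec.shaft_outer_diameter + 2.0 * spec.lateral_margin
    n_xy = int(np.ceil(fov / p))
    n_z = int(np.ceil(spec.shaft_length / p))
    # voxel-centre coordinates, origin at the shaft axis in-plane, 0 axially
    x = (np.arange(n_xy) + 0.5) * p - n_xy * p / 2.0
    y = (np.arange(n_xy) + 0.5) * p - n_xy * p / 2.0
    z = (np.arange(n_z) + 0.5) * p
    return x, y, z, (n_xy, n_xy, n_z)


def generate_phantom(spec: PhantomSpec) -> tuple[CalibratedVolume, PhantomTruth]:
    """Voxelize a phantom and return the density volume plus exact truth.

    Callus is accreted periosteally, shell by shell (in order of radial
    distance from the shaft axis) on the requested side within the
    compartment's axial extent, until the voxelized volume is the closest
    achievable to ``target_volume``.  Noiseless voxel values equal the
    compartment densities exactly; the truth records achieved (voxelized)
    volumes, not the requested targets.

    Raises
    ------
    PhantomSizingError
        If a compartment cannot reach its target volume inside the field
        of view, naming the limiting dimension.
    """
    x, y, z, shape = _grids(spec)
    p = spec.voxel_pitch
    vox_ccm = p**3 / 1000.0  # mm^3 -> cm^3

    X = x[:, None]
    Y = y[None, :]
    r2 = X**2 + Y**2  # in-plane squared radius, (n, n)
    r_out = spec.shaft_outer_diameter / 2.0
    r_in = spec.shaft_inner_diameter / 2.0

    labels = np.zeros(shape, dtype=np.uint8)
    gap_lo, gap_hi = spec.gap_bounds
    in_gap = (z >= gap_lo) & (z < gap_hi)

    cortex_2d = (r2 <= r_out**2) & (r2 > r_in**2)
    marrow_2d = r2 <= r_in**2
    labels[:, :, ~in_gap] = np.where(
        cortex_2d, LBL_CORTICAL, np.where(marrow_2d, LBL_MARROW, LBL_BACKGROUND)
    )[:, :, None]

    cis_normal = np.array([1.0, 0.0, 0.0])

    # periosteal callus accretion
    centre_z = spec.shaft_length / 2.0
    for comp in spec.callus_compartments:
        z_lo = centre_z - comp.axial_extent / 2.0
        z_hi = centre_z + comp.axial_extent / 2.0
        in_extent = (z >= z_lo) & (z < z_hi)
        n_slices = int(in_extent.sum())
        if n_slices == 0:
            raise PhantomSizingError(
                f"axial_extent {comp.axial_extent} mm of the {comp.side} compartment "
                f"covers no slice at pitch {p} mm (limiting dimension: axial extent)"
            )
        side_2d = (X + 0.0 * Y) > 0 if comp.side == "cis" else (X + 0.0 * Y) <= 0
        candidate_2d = (r2 > r_out**2) & side_2d
        # shell-wise accretion: voxels sorted by radial distance, ties broken
        # deterministically by index
        flat_idx = np.flatnonzero(candidate_2d)
        order = np.argsort(r2.ravel()[flat_idx], kind="stable")
        flat_idx = flat_idx[order]
        target_mm3 = comp.target_volume * 1000.0
        n_needed = int(round(target_mm3 / (p**3 * n_slices)))
        n_needed = max(n_needed, 1)
        if n_needed > flat_idx.size:
            raise PhantomSizingError(
                f"{comp.side} compartment target {comp.target_volume} ccm needs "
                f"{n_needed} in-plane voxels but only {flat_idx.size} fit "
                f"(limiting dimension: lateral field of view "
                f"{shape[0] * p:.1f} mm)"
            )
        take = flat_idx[:n_needed]
        sel_2d = np.zeros(candidate_2d.shape, dtype=bool)
        sel_2d.ravel()[take] = True
        lbl = LBL_CALLUS_CIS if comp.side == "cis" else LBL_CALLUS_TRANS
        region = sel_2d[:, :, None] & in_extent[None, None, :]
        # accrete only into background (never overwrite bone/marrow/other callus)
        region &= labels == LBL_BACKGROUND
        labels[region] = lbl

    # screws: cylinders along the cis normal (first axis), through the bone
    if spec.include_metal:
        r_screw = spec.screw_diameter / 2.0
        for z_s in spec.screw_axial_positions:
            screw = (y[:, None] ** 2 + (z[None, :] - z_s) ** 2) <= r_screw**2  # (n, nz)
            within = np.abs(x) <= r_out  # screw spans the bone diameter
            region = within[:, None, None] & screw[None, :, :]
            labels[region] = LBL_METAL

    density_of = {
        LBL_BACKGROUND: 0.0,
        LBL_MARROW: spec.marrow_density,
        LBL_CORTICAL: spec.cortical_density,
        LBL_METAL: spec.metal_density,
    }
    values = np.zeros(shape, dtype=np.float64)
    for lbl, dens in density_of.items():
        values[labels == lbl] = dens
    for comp in spec.callus_compartments:
        lbl = LBL_CALLUS_CIS if comp.side == "cis" else LBL_CALLUS_TRANS
        values[labels == lbl] = comp.density

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=shape)

    counts = np.bincount(labels.ravel(), minlength=6)
    true_volumes = {LABEL_NAMES[i]: float(counts[i]) * vox_ccm for i in range(6)}
    true_densities = {
        LABEL_NAMES[LBL_MARROW]: spec.marrow_density,
        LABEL_NAMES[LBL_CORTICAL]: spec.cortical_density,
    }
    for comp in spec.callus_compartments:
        name = "callus_cis" if comp.side == "cis" else "callus_trans"
        true_densities[name] = comp.density
    if spec.include_metal:
        true_densities["metal"] = spec.metal_density

    volume = CalibratedVolume(values, (p, p, p))
    truth = PhantomTruth(
        label_volume=labels,
        true_volumes=true_volumes,
        true_densities=true_densities,
        cis_halfspace_normal=cis_normal,
        gap_bounds=spec.gap_bounds,
        screw_axial_positions=list(spec.screw_axial_positions or []),
        voxel_pitch=(p, p, p),
    )
    return volume, truth


# ---------------------------------------------------------------------------
# torsion curves
# ---------------------------------------------------------------------------


@dataclass
class TorsionCurveSpec:
    """Piecewise torque–angle curve of a non-destructive torsion test.

    The curve has a quadratic toe-in region of ``toe_extent`` degrees, a
    linear region of slope ``stiffness``, a post-yield region of slope
    ``post_yield_slope`` from ``yield_torque`` up to ``failure_angle``,
    then an instantaneous torque drop of ``failure_drop`` (the machine's
    stop criterion).  Sampled at ``sampling_rate`` Hz under angular
    displacement control at ``angular_rate`` degree/min.
    """

    stiffness: float  # Nm/degree
    toe_extent: float = 0.0  # degree
    yield_torque: float = 37.0  # Nm
    post_yield_slope: float = 0.3  # Nm/degree
    failure_angle: float = 10.0  # degree
    failure_drop: float = 3.0  # Nm
    sampling_rate: float = 20.0  # Hz
    angular_rate: float = 5.0  # degree/min
    noise_sd: float = 0.0  # Nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError("stiffness must be > 0")
        if self.failure_drop < 3.0:
            raise ValueError("failure_drop must be >= 3.0 Nm to trigger the stop criterion")
        if self.toe_extent < 0 or self.yield_torque <= 0:
            raise ValueError("toe_extent must be >= 0 and yield_torque > 0")
        if self.failure_angle <= self.toe_extent:
            raise ValueError("failure_angle lies inside the toe region")
        if self.yield_angle >= self.failure_angle:
            raise ValueError("yield occurs at or beyond the failure angle")

    @property
    def angle_step(self) -> float:
        """Angle increment per sample, degrees."""
        return self.angular_rate / 60.0 / self.sampling_rate

    @property
    def yield_angle(self) -> float:
        # linear region: tau = stiffness * (theta - toe_extent/2)
        return self.toe_extent / 2.0 + self.yield_torque / self.stiffness

    def torque_at(self, theta: np.ndarray) -> np.ndarray:
        """Noiseless torque (Nm) at angles ``theta`` (deg), pre-failure."""
        theta = np.asarray(theta, dtype=np.float64)
        k, toe = self.stiffness, self.toe_extent
        tau = np.where(
            (toe > 0) & (theta < toe),
            k * theta**2 / (2.0 * toe) if toe > 0 else 0.0,
            k * (theta - toe / 2.0),
        )
        th_y = self.yield_angle
        post = self.yield_torque + self.post_yield_slope * (theta - th_y)
        return np.where(theta > th_y, post, tau)

    @property
    def ultimate_torque(self) -> float:
        return float(self.torque_at(np.array(self.failure_angle)))

    @property
    def energy_to_failure(self) -> float:
        """Closed-form integral of torque over angle up to failure, Nm*degree."""
        k, toe = self.stiffness, self.toe_extent
        th_y = self.yield_angle
        e_toe = k * toe**2 / 6.0
        e_lin = k / 2.0 * ((th_y - toe / 2.0) ** 2 - (toe / 2.0) ** 2)
        e_post = (self.yield_torque + self.ultimate_torque) / 2.0 * (self.failure_angle - th_y)
        return e_toe + e_lin + e_post

    def truth_metrics(self) -> dict[str, float]:
        return {
            "stiffness": self.stiffness,
            "yield_torque": self.yield_torque,
            "ultimate_torque": self.ultimate_torque,
            "rotation_to_failure": self.failure_angle,
            "energy_to_failure": self.energy_to_failure,
        }


def generate_torsion_curve(spec: TorsionCurveSpec, post_failure_samples: int = 8):
    """Sample a torsion curve from its spec; returns ``(curve, truth)``.

    ``truth`` is the dict of the five closed-form metrics.  After the drop
    at ``failure_angle`` the torque stays at ``ultimate - failure_drop``
    for a few samples (the machine coasting to a stop).
    """
    from .torsion import TorsionCurve  # local import to avoid cycle

    step = spec.angle_step
    n_pre = int(np.floor(spec.failure_angle / step)) + 1
    theta = np.arange(n_pre + post_failure_samples) * step
    tau = spec.torque_at(theta[:n_pre])
    dropped = spec.ultimate_torque - spec.failure_drop
    tau = np.concatenate([tau, np.full(post_failure_samples, dropped)])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        tau = tau + rng.normal(0.0, spec.noise_sd, size=tau.shape)
    curve = TorsionCurve(
        angle=theta,
        torque=tau,
        sampling_rate=spec.sampling_rate,
        angular_rate=spec.angular_rate,
    )
    return curve, spec.truth_metrics()


# ---------------------------------------------------------------------------
# group datasets
# ---------------------------------------------------------------------------


def sample_compartment_volumes(
    base_volumes: dict[str, float],
    multiplier: float,
    cv: float,
    n: int,
    rng: np.random.Generator,
) -> list[dict[str, float]]:
    """Draw per-sample compartment target volumes (ccm).

    Each compartment volume is ``base * multiplier * L`` with ``L``
    lognormal with unit median and coefficient of variation ``cv``
    (``cv = 0`` gives exact multiples).  One independent draw per sample
    per compartment.
    """
    if multiplier <= 0:
        raise ValueError("effect multiplier must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    sigma = np.sqrt(np.log1p(cv**2))
    out = []
    for _ in range(n):
        draws = {}
        for name, base in base_volumes.items():
            factor = float(rng.lognormal(mean=0.0, sigma=sigma)) if cv > 0 else 1.0
            draws[name] = base * multiplier * factor
        out.append(draws)
    return out


def generate_group_dataset(
    group_specs: dict[str, tuple[PhantomSpec, float]],
    n_per_group: int,
    seed: int,
    cv: float = 0.25,
) -> list[tuple[CalibratedVolume, PhantomTruth, str]]:
    """Generate a full study dataset: ``n_per_group`` phantoms per group.

    ``group_specs`` maps group label to ``(template spec, effect
    multiplier)``; each sample's compartment target volumes are the
    template's scaled by the multiplier and a lognormal factor of
    coefficient of variation ``cv`` (default 0.25, the order of the
    between-animal variation of callus volume in plated-osteotomy
    studies).  Samples are reproducible from ``seed``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    out = []
    ss = np.random.SeedSequence(seed)
    group_seeds = ss.spawn(len(group_specs))
    for (label, (template, multiplier)), gseed in zip(
        sorted(group_specs.items()), group_seeds
    ):
        rng = np.random.default_rng(gseed)
        base = {
            f"{c.side}_{i}": c.target_volume
            for i, c in enumerate(template.callus_compartments)
        }
        draws = sample_compartment_volumes(base, multiplier, cv, n_per_group, rng)
        noise_seeds = rng.integers(0, 2**31 - 1, size=n_per_group)
        for j in range(n_per_group):
            comps = [
                CallusCompartmentSpec(
                    side=c.side,
                    target_volume=draws[j][f"{c.side}_{i}"],
                    density=c.density,
                    axial_extent=c.axial_extent,
                )
                for i, c in enumerate(template.callus_compartments)
            ]
            spec_j = PhantomSpec(
                shaft_outer_diameter=template.shaft_outer_diameter,
                shaft_inner_diameter=template.shaft_inner_diameter,
                shaft_length=template.shaft_length,
                gap_width=template.gap_width,
                voxel_pitch=template.voxel_pitch,
                cortical_density=template.cortical_density,
                marrow_density=template.marrow_density,
                callus_compartments=comps,
                screw_axial_positions=list(template.screw_axial_positions or []) or None,
                include_metal=template.include_metal,
                metal_density=template.metal_density,
                lateral_margin=template.lateral_margin,
                noise_sd=template.noise_sd,
                seed=int(noise_seeds[j]),
            )
            vol, truth = generate_phantom(spec_j)
            out.append((vol, truth, label))
    return out
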
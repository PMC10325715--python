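"""Generation parameters for the synthetic vertical-lobe circuit.

The defaults encode the measured properties of the circuit this package
analyzes: the per-type counts of reconstructed processes, the single-SFL
input rule for SAMs, the large/small bouton volume components, the sparse
large-bouton placement rate and the per-type soma geometry.  Changing them
produces "what-if" circuits; leaving them alone reproduces the study
conditions the analyses are validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping


class ConfigError(ValueError):
    """Raised for an internally inconsistent generation configuration."""


#: Per-type counts of the reconstructed cell processes (SFL axons, seed and
#: non-seed amacrines, LN processes, CIN fibers, the two AF subclasses
#: pooled, NM processes).
DEFAULT_N_PER_TYPE: dict[str, int] = {
    "SFL": 84,
    "SAM": 108,
    "CAM": 53,
    "LN": 24,
    "CIN": 55,
    "AF": 32,
    "NM": 88,
}

#: Soma-volume sampling parameters per cortex class, µm³.  SAM and CAM are
#: truncated normals (mean, sd); LN volumes are highly variable and drawn
#: uniformly over the observed range; "Other" covers glia/progenitor-like
#: cells for which no volume statistics exist and uses a broad truncated
#: normal chosen to overlap SAM/CAM in volume (they are separated by shape,
#: not size).
DEFAULT_SOMA_VOLUME_PARAMS: dict[str, dict] = {
    "SAM": {"dist": "truncnorm", "mean": 207.7, "sd": 26.1},
    "CAM": {"dist": "truncnorm", "mean": 337.2, "sd": 41.6},
    "LN": {"dist": "uniform", "low": 464.0, "high": 2850.0},
    "Other": {"dist": "truncnorm", "mean": 400.0, "sd": 180.0},
}

#: Relative ellipsoid semi-axis ratios per class (before volume scaling).
#: SAM somata are roundish, CAM slightly elongated, LN moderately elongated,
#: "Other" strongly elongated — producing the sphericity ordering
#: SAM > CAM > Other that the morphometric classifier exploits.
DEFAULT_SOMA_AXIS_RATIOS: dict[str, tuple[float, float, float]] = {
    "SAM": (1.0, 0.95, 0.90),
    "CAM": (1.5, 1.0, 0.85),
    "LN": (1.8, 1.0, 0.9),
    "Other": (3.5, 1.0, 0.8),
}

#: Input mix of CAM dendritic trees (fraction of in-synapses per source type).
DEFAULT_CAM_INPUT_MIX: dict[str, float] = {"SFL": 0.48, "SAM": 0.42, "CIN": 0.05, "NM": 0.05}

#: Output mix of SAM neuritic trunks over targets other than CAMs, from the
#: identified seed-cell output counts 109 LN : 70 AF : 2 NM.  SAM->CAM edges
#: are drawn from the CAM in-degree side instead, so they are excluded here.
DEFAULT_SAM_OUTPUT_MIX: dict[str, float] = {
    "LN": 109 / 181,
    "AF": 70 / 181,
    "NM": 2 / 181,
}


@dataclass
class GenerationConfig:
    """All knobs of the synthetic-circuit generators.

    Attributes
    ----------
    n_per_type
        Number of neurons per cell type.
    sfl_tract_length
        Length (µm) of the SFL axon segments crossing the volume.
    lb_rate, sb_rate
        Large/small bouton linear densities per 100 µm of SFL axon.
    lb_volume_mean, lb_volume_sd, sb_volume_mean, sb_volume_sd
        Components (µm³) of the bimodal bouton-volume distribution.
    cam_in_degree_range
        Inclusive range of CAM synaptic in-degree; drawn log-uniformly
        ("dozens to hundreds", observed maximum 514).
    cin_sites_per_bouton_median
        Median number of polyadic sites per CIN bouton.
    sam_out_degree_mean
        Mean number of SAM output sites onto non-CAM targets (Poisson).
    n_reciprocal_af_pairs
        Reciprocal AF-AF synapse pairs inserted post hoc — the only source
        of directed cycles in a generated circuit.
    soma_volume_params, soma_axis_ratios, soma_axis_jitter
        Per-class soma geometry; jitter is a relative sd on axis ratios.
    voxel_size_nm
        Imaging voxel (x, y, z) in nm.
    soma_voxel_size_nm
        Voxel used to rasterize soma masks (coarser than the imaging voxel;
        a ~200 µm³ soma at full imaging resolution would be ~10⁸ voxels).
    seed
        Seed for all randomness; a fixed seed gives byte-identical output.
    """

    n_per_type: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_TYPE))
    sfl_tract_length: float = 260.0
    lb_rate: float = 1.03
    sb_rate: float = 1.03 * (109 / 45)
    lb_volume_mean: float = 6.41
    lb_volume_sd: float = 2.1
    sb_volume_mean: float = 0.95
    sb_volume_sd: float = 0.88
    cam_in_degree_range: tuple[int, int] = (30, 514)
    cin_sites_per_bouton_median: float = 2.3
    sam_out_degree_mean: float = 181 / 28
    cam_input_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CAM_INPUT_MIX))
    sam_output_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SAM_OUTPUT_MIX))
    n_reciprocal_af_pairs: int = 4
    soma_volume_params: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SOMA_VOLUME_PARAMS.items()}
    )
    soma_axis_ratios: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SOMA_AXIS_RATIOS)
    )
    soma_axis_jitter: float = 0.05
    voxel_size_nm: tuple[float, float, float] = (8.0, 8.0, 30.0)
    soma_voxel_size_nm: tuple[float, float, float] = (256.0, 256.0, 240.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for t, n in self.n_per_type.items():
            if n < 0:
                raise ConfigError(f"negative count for type {t}: {n}")
        for name in (
            "sfl_tract_length",
            "lb_rate",
            "sb_rate",
            "lb_volume_mean",
            "lb_volume_sd",
            "sb_volume_mean",
            "sb_volume_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        lo, hi = self.cam_in_degree_range
        if not (0 < lo <= hi):
            raise ConfigError(f"invalid cam_in_degree_range {self.cam_in_degree_range}")
        if self.n_reciprocal_af_pairs < 0:
            raise ConfigError("n_reciprocal_af_pairs must be >= 0")
        n_af = self.n_per_type.get("AF", 0)
        if self.n_reciprocal_af_pairs > n_af * (n_af - 1) // 2:
            raise ConfigError(
                f"{self.n_reciprocal_af_pairs} reciprocal pairs requested but only "
                f"{n_af} AF neurons available"
            )
        if any(v <= 0 for v in self.voxel_size_nm) or any(
            v <= 0 for v in self.soma_voxel_size_nm
        ):
            raise ConfigError("voxel sizes must be positive")
        # Each SAM needs one large bouton; the expected LB supply of the SFL
        # population at the configured rate and tract length must cover it.
        n_sam = self.n_per_type.get("SAM", 0)
        capacity = self.n_per_type.get("SFL", 0) * self.lb_rate * self.sfl_tract_length / 100.0
        if n_sam > 0 and n_sam > capacity:
            raise ConfigError(
                f"{n_sam} SAMs requested but the SFL population supplies only "
                f"~{capacity:.0f} large boutons at rate {self.lb_rate}/100 µm over "
                f"{self.sfl_tract_length} µm"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenerationConfig":
        d = dict(d)
        if "cam_in_degree_range" in d:
            d["cam_in_degree_range"] = tuple(d["cam_in_degree_range"])
        for key in ("voxel_size_nm", "soma_voxel_size_nm"):
            if key in d:
                d[key] = tuple(d[key])
        if "soma_axis_ratios" in d:
            d["soma_axis_ratios"] = {k: tuple(v) for k, v in d["soma_axis_ratios"].items()}
        return cls(**d)
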
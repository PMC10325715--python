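"""Synthetic vertical-lobe circuit generation.

Emulates the statistical structure of the measured circuit so every analysis
stage can be exercised without electron-microscopy data:

* a wiring table following the seven-cell-type connectivity rules — one SFL
  input per SAM, CAMs integrating dozens to hundreds of inputs, SAM+CAM
  convergence onto LNs, CIN polyadic boutons onto CAMs, no SFL-to-LN
  contacts — acyclic by construction except for a configurable number of
  reciprocal AF-AF synapse pairs;
* rasterized ellipsoidal soma masks with per-type volume distributions and
  axis ratios;
* boutons along afferent axons with Poisson large-bouton placement and the
  bimodal large/small volume components;
* rasterized tube/tree volumes of known centerline length, the fixtures for
  the wire-length pipeline.

All generators are deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .boutons import BoutonSeries
from .config import ConfigError, GenerationConfig
from .morphometry import CellBodyMask
from .tables import ALLOWED_EDGE_TYPES, ConnectomeTable

#: Feed-forward ordering of the cell types: every generated edge except the
#: explicitly inserted AF-AF reciprocal contacts points forward in this list.
TYPE_ORDER = ("SFL", "CIN", "SAM", "NM", "CAM", "AF", "LN")

#: Extent (µm) of the reconstructed region the synthetic circuit mimics.
ROI_EXTENT_UM = (260.0, 390.0, 27.0)

#: Mean number of en-passant output boutons per CAM axon onto LN processes.
CAM_OUT_DEGREE_MEAN = 10.0

#: Mean number of CIN-to-AF synapses per CIN fiber (CINs "less often"
#: innervate AFs).
CIN_AF_OUT_MEAN = 0.5


# ---------------------------------------------------------------------------
# Wiring
# ---------------------------------------------------------------------------

def _assign_ids(n_per_type: dict[str, int]) -> pd.DataFrame:
    rows = []
    next_id = 0
    for t in TYPE_ORDER:
        for _ in range(n_per_type.get(t, 0)):
            rows.append((next_id, t))
            next_id += 1
    return pd.DataFrame(rows, columns=["neuron_id", "cell_type"])


def generate_connectome(config: GenerationConfig) -> ConnectomeTable:
    """Generate a synthetic wiring table obeying the circuit rules.

    Construction order (all draws from one seeded generator, so output is
    reproducible bit-for-bit):

    1. every SAM receives exactly one SFL synapse at its palm (large
       bouton);
    2. each CAM draws a log-uniform in-degree and fills it from SFLs, SAMs,
       CINs and NMs at the configured input mix (CIN synapses are polyadic);
    3. each SAM distributes additional outputs over LNs, AFs and NMs;
    4. each CAM innervates LNs en passant; each CIN occasionally contacts
       AFs;
    5. ``n_reciprocal_af_pairs`` disjoint AF pairs receive one synapse in
       each direction — the only directed cycles in the table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    neurons = _assign_ids(config.n_per_type)
    ids_by_type = {
        t: neurons.loc[neurons["cell_type"] == t, "neuron_id"].to_numpy() for t in TYPE_ORDER
    }

    pre: list[int] = []
    post: list[int] = []
    n_sites: list[int] = []
    compartment: list[str] = []

    def add(p: int, q: int, k: int = 1, comp: str = "") -> None:
        pre.append(int(p))
        post.append(int(q))
        n_sites.append(int(k))
        compartment.append(comp)

    sfl, sam, cam = ids_by_type["SFL"], ids_by_type["SAM"], ids_by_type["CAM"]
    ln, cin, af, nm = ids_by_type["LN"], ids_by_type["CIN"], ids_by_type["AF"], ids_by_type["NM"]

    # 1. one SFL large-bouton input per SAM, at the palm
    if len(sam) and not len(sfl):
        raise ConfigError("SAMs require at least one SFL axon")
    for s in sam:
        add(rng.choice(sfl), s, 1, "LB")

    # 2. CAM dendritic in-degree
    lo, hi = config.cam_in_degree_range
    mix_types = [t for t in ("SFL", "SAM", "CIN", "NM") if len(ids_by_type[t])]
    mix_p = np.array([config.cam_input_mix.get(t, 0.0) for t in mix_types], dtype=float)
    if len(cam) and (not len(mix_types) or mix_p.sum() <= 0):
        raise ConfigError("CAMs present but no input sources configured")
    if len(mix_types):
        mix_p = mix_p / mix_p.sum()
    cin_extra_mean = max(config.cin_sites_per_bouton_median - 1.0, 0.0)
    for c in cam:
        deg = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        counts = rng.multinomial(deg, mix_p)
        for t, k in zip(mix_types, counts):
            partners = rng.choice(ids_by_type[t], size=k)
            for p in partners:
                if t == "CIN":  # polyadic boutons
                    add(p, c, 1 + rng.poisson(cin_extra_mean), "")
                else:
                    add(p, c, 1, "SB" if t == "SFL" else "")

    # 3. SAM outputs onto LN / AF / NM
    out_types = [t for t in ("LN", "AF", "NM") if len(ids_by_type[t])]
    out_p = np.array([config.sam_output_mix.get(t, 0.0) for t in out_types], dtype=float)
    if len(out_types) and out_p.sum() > 0:
        out_p = out_p / out_p.sum()
        for s in sam:
            counts = rng.multinomial(rng.poisson(config.sam_out_degree_mean), out_p)
            for t, k in zip(out_types, counts):
                for p in rng.choice(ids_by_type[t], size=k):
                    add(s, p, 1, "")

    # 4. CAM->LN en-passant outputs; occasional CIN->AF contacts
    if len(ln):
        for c in cam:
            for p in rng.choice(ln, size=rng.poisson(CAM_OUT_DEGREE_MEAN)):
                add(c, p, 1, "")
    if len(af):
        for c in cin:
            for p in rng.choice(af, size=rng.poisson(CIN_AF_OUT_MEAN)):
                add(c, p, 1 + rng.poisson(cin_extra_mean), "")

    # 5. reciprocal AF-AF pairs: the only cycles
    if config.n_reciprocal_af_pairs:
        chosen = rng.choice(af, size=2 * config.n_reciprocal_af_pairs, replace=False)
        for a, b in chosen.reshape(-1, 2):
            add(a, b, 1, "")
            add(b, a, 1, "")

    n_rows = len(pre)
    ext = np.asarray(ROI_EXTENT_UM)
    xyz = rng.uniform(0, 1, size=(n_rows, 3)) * ext
    synapses = pd.DataFrame(
        {
            "pre_id": pre,
            "post_id": post,
            "n_sites": n_sites,
            "x_um": xyz[:, 0],
            "y_um": xyz[:, 1],
            "z_um": xyz[:, 2],
            "compartment": compartment,
        }
    )
    table = ConnectomeTable(neurons=neurons, synapses=synapses, meta={"config": config.to_dict()})
    table.validate()
    extra = table.edge_type_pairs() - ALLOWED_EDGE_TYPES
    assert not extra, f"generator produced disallowed edge types {extra}"
    return table


# ---------------------------------------------------------------------------
# Soma populations
# ---------------------------------------------------------------------------

#: Default class mix of a generated soma population: the 110-cell
#: expert-typed training set (69 SAM, 16 CAM, 7 LN, 18 Other).
TRAINING_SET_MIX = {"SAM": 69, "CAM": 16, "LN": 7, "Other": 18}

#: Observed cortex composition used for census recovery experiments.
CORTEX_FRACTIONS = {"SAM": 0.893, "CAM": 0.016, "LN": 0.006, "Other": 0.085}


def _sample_volume(params: dict, rng: np.random.Generator) -> float:
    if params["dist"] == "uniform":
        return float(rng.uniform(params["low"], params["high"]))
    mean, sd = params["mean"], params["sd"]
    if sd == 0:
        return float(mean)
    a = (0.0 - mean) / sd  # truncate at zero
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def rasterize_ellipsoid(
    semi_axes_um: np.ndarray,
    rotation: np.ndarray,
    voxel_size_nm: tuple[float, float, float],
) -> np.ndarray:
    """Voxel indices of an ideal solid ellipsoid centered on the grid.

    A voxel belongs to the mask when its center lies inside the rotated
    ellipsoid.  Returns an (M, 3) integer array.
    """
    vx = np.asarray(voxel_size_nm, dtype=float) / 1000.0  # µm
    # half-extent of the rotated ellipsoid along each grid axis
    half = np.sqrt(((rotation * semi_axes_um) ** 2).sum(axis=1))
    n = np.ceil(half / vx).astype(int) + 1
    axes = [np.arange(-k, k + 1) * v for k, v in zip(n, vx)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)  # physical coords, µm
    local = pts @ rotation  # into principal frame
    inside = ((local / semi_axes_um) ** 2).sum(axis=-1) <= 1.0
    idx = np.argwhere(inside)
    return idx  # nonnegative voxel indices within the local grid


def generate_soma_population(
    config: GenerationConfig,
    n_per_class: dict[str, int] | None = None,
    seed: int | None = None,
) -> list[CellBodyMask]:
    """Rasterized soma masks with per-class volumes, shapes and true labels.

    Volumes follow the configured per-class distributions (truncated at 0);
    axis ratios per class produce the sphericity ordering SAM > CAM > Other.
    By default the population reproduces the 110-cell training mix; pass
    ``n_per_class`` for other compositions.

    Raises :class:`~vlconn.config.ConfigError` when the soma voxel is too
    coarse to resolve the smallest class mean with at least 50 voxels.
    """
    counts = dict(TRAINING_SET_MIX if n_per_class is None else n_per_class)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    voxel_vol = float(np.prod(np.asarray(config.soma_voxel_size_nm) / 1000.0))
    smallest = min(
        (p["mean"] if p["dist"] == "truncnorm" else p["low"])
        for t, p in config.soma_volume_params.items()
        if counts.get(t, 0) > 0
    )
    if smallest / voxel_vol < 50:
        raise ConfigError(
            f"soma voxel {config.soma_voxel_size_nm} nm too coarse: smallest soma "
            f"(~{smallest:.0f} µm³) would span under 50 voxels"
        )
    masks: list[CellBodyMask] = []
    cell_id = 0
    for cls in sorted(counts):
        params = config.soma_volume_params[cls]
        base_ratio = np.asarray(config.soma_axis_ratios[cls], dtype=float)
        for _ in range(counts[cls]):
            vol = _sample_volume(params, rng)
            ratio = base_ratio
            if config.soma_axis_jitter > 0:
                ratio = base_ratio * np.exp(
                    rng.normal(0, config.soma_axis_jitter, size=3)
                )
            scale = (3 * vol / (4 * np.pi * np.prod(ratio))) ** (1 / 3)
            semi = np.sort(scale * ratio)[::-1]
            rot = _random_rotation(rng)
            vox = rasterize_ellipsoid(semi, rot, config.soma_voxel_size_nm)
            masks.append(
                CellBodyMask(
                    voxels=vox,
                    voxel_size_nm=config.soma_voxel_size_nm,
                    cell_id=cell_id,
                    true_type=cls,
                )
            )
            cell_id += 1
    return masks


# ---------------------------------------------------------------------------
# Bouton series
# ---------------------------------------------------------------------------

def _truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    if size == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_bouton_series(
    config: GenerationConfig,
    axon_length: float,
    axon_id: int = 0,
    seed: int | None = None,
) -> BoutonSeries:
    """Boutons along one afferent axon.

    Large-bouton positions follow a homogeneous Poisson process at
    ``lb_rate`` per 100 µm (small boutons likewise at ``sb_rate``); volumes
    come from the two truncated-normal components.  True LB/SB labels are
    retained for classifier validation.
    """
    if axon_length <= 0:
        raise ValueError("axon_length must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for cls, rate, mean, sd in (
        ("LB", config.lb_rate, config.lb_volume_mean, config.lb_volume_sd),
        ("SB", config.sb_rate, config.sb_volume_mean, config.sb_volume_sd),
    ):
        n = rng.poisson(rate * axon_length / 100.0) if rate > 0 else 0
        pos = np.sort(rng.uniform(0, axon_length, size=n))
        vol = _truncated_normal(mean, sd, n, rng)
        for p, v in zip(pos, vol):
            rows.append({"position_um": p, "volume_um3": v, "true_class": cls})
    boutons = (
        pd.DataFrame(rows).sort_values("position_um").reset_index(drop=True)
        if rows
        else pd.DataFrame(columns=["position_um", "volume_um3", "true_class"])
    )
    return BoutonSeries(axon_id=axon_id, length_um=float(axon_length), boutons=boutons)


# ---------------------------------------------------------------------------
# Tube / tree volumes for wire-length validation
# ---------------------------------------------------------------------------

@dataclass
class TubeVolume:
    """Binary voxel mask of a tube or tree with its analytic length."""

    volume: np.ndarray  # uint8, indexed (x, y, z)
    voxel_size_nm: tuple[float, float, float]
    true_length_um: float
    has_cycle: bool
    origin_um: np.ndarray


def _paths_cycle_and_length(paths: list[np.ndarray]) -> tuple[float, bool]:
    length = 0.0
    nodes: dict[tuple, int] = {}
    edges: set[tuple[int, int]] = set()

    def node(p: np.ndarray) -> int:
        key = tuple(np.round(p, 6))
        return nodes.setdefault(key, len(nodes))

    for path in paths:
        for a, b in zip(path[:-1], path[1:]):
            seg = float(np.linalg.norm(b - a))
            length += seg
            u, v = node(a), node(b)
            edges.add((min(u, v), max(u, v)))
    # independent cycles = E - V + number of components
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    g.add_edges_from(edges)
    cyc = g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g) > 0
    return length, cyc


def generate_tube_volume(
    paths: np.ndarray | list[np.ndarray],
    radius_um: float,
    voxel_size_nm: tuple[float, float, float] = (1000.0, 1000.0, 1000.0),
    shape: tuple[int, int, int] | None = None,
) -> TubeVolume:
    """Rasterize tubes of constant radius around polyline centerlines.

    ``paths`` is one (K, 3) array of µm points or a list of them; paths
    sharing endpoints form trees (or cycles, flagged in the output).  The
    analytic centerline length is recorded as ground truth for the
    skeleton-based wire-length estimator.

    When ``shape`` is given the volume must fit inside it, else an error is
    raised; otherwise the grid is sized to the geometry.
    """
    if isinstance(paths, np.ndarray):
        paths = [paths]
    paths = [np.asarray(p, dtype=float) for p in paths]
    for p in paths:
        if p.ndim != 2 or p.shape[1] != 3 or len(p) < 2:
            raise ValueError("each path needs >= 2 three-dimensional points")
    vx = np.asarray(voxel_size_nm, dtype=float) / 1000.0
    if radius_um < vx.min():
        raise ValueError("radius must be at least one voxel")
    all_pts = np.vstack(paths)
    margin = radius_um + 2 * vx
    origin = all_pts.min(axis=0) - margin
    extent = all_pts.max(axis=0) + margin - origin
    dims = np.ceil(extent / vx).astype(int) + 1
    if shape is not None:
        if np.any(dims > np.asarray(shape)):
            raise ValueError(f"path plus radius needs grid {tuple(dims)}, exceeds shape {shape}")
        dims = np.asarray(shape)
    vol = np.zeros(tuple(dims), dtype=np.uint8)

    for path in paths:
        for a, b in zip(path[:-1], path[1:]):
            lo = np.floor((np.minimum(a, b) - margin - origin) / vx).astype(int)
            hi = np.ceil((np.maximum(a, b) + margin - origin) / vx).astype(int) + 1
            lo = np.clip(lo, 0, dims - 1)
            hi = np.clip(hi, 1, dims)
            axes = [origin[k] + np.arange(lo[k], hi[k]) * vx[k] for k in range(3)]
            gx, gy, gz = np.meshgrid(*axes, indexing="ij")
            pts = np.stack([gx, gy, gz], axis=-1)
            d = b - a
            denom = float(d @ d)
            t = np.clip(((pts - a) @ d) / denom, 0.0, 1.0) if denom > 0 else 0.0
            closest = a + t[..., None] * d
            dist2 = ((pts - closest) ** 2).sum(axis=-1)
            sub = vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            sub |= (dist2 <= radius_um**2).astype(np.uint8)

    length, cyc = _paths_cycle_and_length(paths)
    return TubeVolume(
        volume=vol,
        voxel_size_nm=tuple(voxel_size_nm),
        true_length_um=length,
        has_cycle=cyc,
        origin_um=origin,
    )
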
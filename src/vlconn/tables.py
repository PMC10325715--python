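"""Tabular containers for connectome data.

A connectome is represented as two tables: a neuron table (id, cell type)
and a directed synapse table (pre id, post id, number of synaptic sites,
position, optional compartment tag).  All graph statistics in the package
start from this representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: The seven neuronal cell types participating in vertical-lobe connectivity:
#: SFL afferent axons, simple and complex amacrine interneurons (SAM, CAM),
#: large efferent neurons (LN), CAM-input-neurons (CIN), ascending fibers (AF)
#: and neuromodulatory fibers (NM).
CELL_TYPES = ("SFL", "SAM", "CAM", "LN", "CIN", "AF", "NM")

#: Additional label used by the morphometric census for cortex cells that are
#: not one of the three main somatic classes (glia, progenitor-like cells ...).
OTHER_TYPE = "Other"

#: Directed (presynaptic type, postsynaptic type) pairs allowed in a generated
#: circuit.  Within this set the type order SFL, CIN, SAM, NM, CAM, AF, LN is
#: strictly feed-forward, so any generated table without explicitly inserted
#: reciprocal AF-AF contacts is acyclic by construction.
ALLOWED_EDGE_TYPES = frozenset(
    {
        ("SFL", "SAM"),
        ("SFL", "CAM"),
        ("CIN", "CAM"),
        ("CIN", "AF"),
        ("SAM", "CAM"),
        ("SAM", "LN"),
        ("SAM", "AF"),
        ("SAM", "NM"),
        ("NM", "CAM"),
        ("CAM", "LN"),
        ("AF", "AF"),
    }
)

NEURON_COLUMNS = ["neuron_id", "cell_type"]
SYNAPSE_COLUMNS = ["pre_id", "post_id", "n_sites", "x_um", "y_um", "z_um", "compartment"]


class ConnectomeError(ValueError):
    """Raised when a neuron/synapse table violates its structural contract."""


@dataclass
class ConnectomeTable:
    """Neuron table plus directed synapse table.

    Parameters
    ----------
    neurons
        DataFrame with columns ``neuron_id`` (int) and ``cell_type``.
    synapses
        DataFrame with columns ``pre_id``, ``post_id``, ``n_sites`` (>= 1),
        ``x_um``, ``y_um``, ``z_um`` and optional ``compartment``
        (e.g. ``LB``, ``SB``, ``palm``).
    allow_autapse
        Whether self-synapses are tolerated by :meth:`validate`.  The real
        circuit contained exactly one SAM autapse, so the flag exists, but
        generated tables never set it.
    """

    neurons: pd.DataFrame
    synapses: pd.DataFrame
    allow_autapse: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.neurons = self.neurons.reset_index(drop=True)
        if "compartment" not in self.synapses.columns:
            self.synapses = self.synapses.assign(compartment="")
        self.synapses = self.synapses.reset_index(drop=True)

    # -- queries -----------------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_synapses(self) -> int:
        """Total number of synaptic sites (sum of ``n_sites``)."""
        return int(self.synapses["n_sites"].sum())

    def types(self) -> pd.Series:
        """Cell type indexed by neuron id."""
        return self.neurons.set_index("neuron_id")["cell_type"]

    def edge_type_pairs(self) -> set[tuple[str, str]]:
        """The set of (pre type, post type) pairs realized in the table."""
        t = self.types()
        pre = self.synapses["pre_id"].map(t)
        post = self.synapses["post_id"].map(t)
        return set(zip(pre, post))

    # -- validation --------------------------------------------------------
    def validate(self) -> "ConnectomeTable":
        """Check structural invariants, raising :class:`ConnectomeError`.

        Checks: unique neuron ids, known cell types, dangling synapse
        references, ``n_sites >= 1`` and (unless ``allow_autapse``) absence
        of self-synapses.
        """
        if self.neurons["neuron_id"].duplicated().any():
            dupes = self.neurons.loc[self.neurons["neuron_id"].duplicated(), "neuron_id"]
            raise ConnectomeError(f"duplicate neuron ids: {sorted(set(dupes))}")
        bad_types = set(self.neurons["cell_type"]) - set(CELL_TYPES) - {OTHER_TYPE}
        if bad_types:
            raise ConnectomeError(
                f"unknown cell types {sorted(bad_types)}; allowed: {CELL_TYPES + (OTHER_TYPE,)}"
            )
        ids = set(self.neurons["neuron_id"])
        for col in ("pre_id", "post_id"):
            dangling = ~self.synapses[col].isin(ids)
            if dangling.any():
                rows = self.synapses.index[dangling].tolist()[:10]
                raise ConnectomeError(
                    f"synapse rows {rows} reference undeclared neurons in column {col!r}"
                )
        if (self.synapses["n_sites"] < 1).any():
            rows = self.synapses.index[self.synapses["n_sites"] < 1].tolist()[:10]
            raise ConnectomeError(f"n_sites < 1 at synapse rows {rows}")
        if not self.allow_autapse:
            self_rows = self.synapses["pre_id"] == self.synapses["post_id"]
            if self_rows.any():
                rows = self.synapses.index[self_rows].tolist()[:10]
                raise ConnectomeError(
                    f"self-synapses at rows {rows} (set allow_autapse=True to permit)"
                )
        return self

    def equals(self, other: "ConnectomeTable") -> bool:
        return self.neurons.equals(other.neurons) and self.synapses.equals(other.synapses)
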
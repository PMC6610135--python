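"""Fixed in-degree bipartite connection graphs and their sparseness.

A common-drive network of ``n_source`` units projects onto ``n_receiver``
cells so that every receiver draws exactly ``k`` distinct presynaptic partners
(constant in-degree). Density is then xi = C / C_max = k / n_source,
independent of the receiver count, and sparseness is its complement
rho = 1 - k / n_source. Because two receivers overlap in a hypergeometric
number of sources, the expected fraction of shared input — and hence the
expected fast-timescale correlation between their membrane potentials — is
simply k / n_source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import as_seedseq

__all__ = [
    "NetworkTopology",
    "MotifSpec",
    "build_fixed_indegree",
    "sparseness",
    "predicted_correlation",
    "indegree_from_sparseness",
    "build_motif",
    "write_edge_list",
    "read_edge_list",
]


@dataclass
class NetworkTopology:
    """Directed source -> receiver graph with constant in-degree.

    ``edges`` is an ndarray of shape (C, 2) holding (source, target) index
    pairs, 0-based within each population. ``sign`` is +1 for excitatory,
    -1 for inhibitory projections.
    """

    n_source: int
    n_receiver: int
    in_degree: int
    edges: np.ndarray
    sign: int = +1
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_source <= 0 or self.n_receiver <= 0:
            raise ValueError("population sizes must be positive")
        if not 1 <= self.in_degree <= self.n_source:
            raise ValueError(
                f"in-degree {self.in_degree} outside [1, {self.n_source}]"
            )
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if e.shape[0] != self.n_receiver * self.in_degree:
            raise ValueError("edge count != n_receiver * in_degree")
        if len({(int(s), int(t)) for s, t in e}) != e.shape[0]:
            raise ValueError("duplicate edges")
        counts = np.bincount(e[:, 1], minlength=self.n_receiver)
        if not np.all(counts == self.in_degree):
            raise ValueError("every receiver must have exactly in_degree edges")
        self.edges = e

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def sources_of(self, receiver: int) -> np.ndarray:
        """Presynaptic partners of one receiver."""
        return self.edges[self.edges[:, 1] == receiver, 0]

    def adjacency(self) -> np.ndarray:
        """Dense boolean (n_source, n_receiver) connection matrix."""
        a = np.zeros((self.n_source, self.n_receiver), dtype=bool)
        a[self.edges[:, 0], self.edges[:, 1]] = True
        return a


@dataclass
class MotifSpec:
    """Parameters of one of the three feedforward/recurrent input motifs.

    motif : {"ff_exc", "ff_inh", "recurrent_inh"}
        Pure feedforward excitation; feedforward excitation plus feedforward
        inhibition through a local interneuron pool; or the latter with the
        interneuron pool recurrently connected to itself (the active
        decorrelation motif).
    rho_drive, rho_inh, rho_rec : float in [0, 1)
        Sparseness of the drive->receiver (and drive->interneuron)
        projection, of the interneuron->receiver projection, and of the
        recurrent interneuron->interneuron graph.
    """

    motif: str
    rho_drive: float = 0.5
    rho_inh: float = 0.9
    rho_rec: float = 0.9
    n_source: int = 100
    n_inh: int = 100
    n_receiver: int = 100

    VALID = ("ff_exc", "ff_inh", "recurrent_inh")

    def __post_init__(self) -> None:
        if self.motif not in self.VALID:
            raise ValueError(f"unknown motif {self.motif!r}; choose from {self.VALID}")
        for label, rho in [("rho_drive", self.rho_drive),
                           ("rho_inh", self.rho_inh),
                           ("rho_rec", self.rho_rec)]:
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"{label}={rho} outside [0, 1)")


def build_fixed_indegree(
    n_source: int,
    n_receiver: int,
    k: int,
    seed,
    sign: int = +1,
    name: str = "",
    exclude_self: bool = False,
) -> NetworkTopology:
    """Draw a constant in-degree graph: each receiver samples ``k`` distinct
    sources uniformly without replacement, independently of other receivers.

    ``exclude_self`` removes the diagonal for recurrent graphs where source
    and receiver index the same population (requires k <= n_source - 1).
    """
    if n_source <= 0 or n_receiver <= 0:
        raise ValueError("population sizes must be positive")
    n_avail = n_source - 1 if exclude_self else n_source
    if not 1 <= k <= n_avail:
        raise ValueError(f"in-degree {k} outside [1, {n_avail}]")
    rng = np.random.default_rng(seed)
    edges = np.empty((n_receiver * k, 2), dtype=np.int64)
    pool = np.arange(n_source)
    for j in range(n_receiver):
        if exclude_self:
            candidates = np.delete(pool, j) if j < n_source else pool
        else:
            candidates = pool
        src = rng.choice(candidates, size=k, replace=False)
        edges[j * k:(j + 1) * k, 0] = src
        edges[j * k:(j + 1) * k, 1] = j
    return NetworkTopology(n_source, n_receiver, k, edges, sign=sign, name=name)


def sparseness(topology: NetworkTopology) -> float:
    """rho = 1 - k / n_source, the complement of graph density."""
    return 1.0 - topology.in_degree / topology.n_source


def predicted_correlation(k: int, n_source: int) -> float:
    """Expected shared-input fraction k / n_source for a receiver pair.

    Two receivers drawing k sources each, uniformly without replacement from
    n_source, share E[overlap] = k^2 / n_source connections out of k inputs
    apiece, so the expected fraction of common input is k / n_source. This is
    the analytic prediction the simulated fast-timescale Vm correlation is
    compared against.
    """
    if not 1 <= k <= n_source:
        raise ValueError(f"in-degree {k} outside [1, {n_source}]")
    return k / n_source


def indegree_from_sparseness(rho: float, n: int) -> int:
    """Integer in-degree for sparseness rho over a population of size n.

    Nearest-integer rounding of (1 - rho) * n, floored at 1 so every receiver
    keeps at least one input.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"sparseness {rho} outside [0, 1)")
    return max(1, round((1.0 - rho) * n))


def build_motif(spec: MotifSpec, seed) -> dict:
    """Build the sub-graphs of one input motif.

    Returns a dict keyed by projection name:

    - ``drive_to_receiver`` (always; excitatory)
    - ``drive_to_inh`` and ``inh_to_receiver`` (ff_inh, recurrent_inh)
    - ``inh_to_inh`` (recurrent_inh only; self-connections excluded)

    Sub-graph seeds are derived from ``seed`` so that motifs sharing a seed
    share their drive->receiver wiring.
    """
    ss = as_seedseq(seed)
    sub = ss.spawn(4)
    k_drive = indegree_from_sparseness(spec.rho_drive, spec.n_source)
    graphs = {
        "drive_to_receiver": build_fixed_indegree(
            spec.n_source, spec.n_receiver, k_drive, sub[0],
            sign=+1, name="drive_to_receiver"),
    }
    if spec.motif in ("ff_inh", "recurrent_inh"):
        graphs["drive_to_inh"] = build_fixed_indegree(
            spec.n_source, spec.n_inh, k_drive, sub[1],
            sign=+1, name="drive_to_inh")
        k_inh = indegree_from_sparseness(spec.rho_inh, spec.n_inh)
        graphs["inh_to_receiver"] = build_fixed_indegree(
            spec.n_inh, spec.n_receiver, k_inh, sub[2],
            sign=-1, name="inh_to_receiver")
    if spec.motif == "recurrent_inh":
        k_rec = indegree_from_sparseness(spec.rho_rec, spec.n_inh)
        graphs["inh_to_inh"] = build_fixed_indegree(
            spec.n_inh, spec.n_inh, k_rec, sub[3],
            sign=-1, name="inh_to_inh", exclude_self=True)
    return graphs


def write_edge_list(topology: NetworkTopology, path) -> None:
    """Serialize as a two-column tab-delimited (source_id, target_id) list."""
    header = (
        f"# topology name={topology.name or 'unnamed'} "
        f"n_source={topology.n_source} n_receiver={topology.n_receiver} "
        f"in_degree={topology.in_degree} sign={topology.sign}\n"
        "source_id\ttarget_id\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for s, t in topology.edges:
            fh.write(f"{s}\t{t}\n")


def read_edge_list(path) -> NetworkTopology:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# topology"):
            raise ValueError(f"{path}: missing topology header")
        meta = dict(tok.split("=") for tok in first[1:].split() if "=" in tok)
        fh.readline()  # column names
        edges = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    return NetworkTopology(
        n_source=int(meta["n_source"]),
        n_receiver=int(meta["n_receiver"]),
        in_degree=int(meta["in_degree"]),
        edges=edges,
        sign=int(meta.get("sign", 1)),
        name=meta.get("name", ""),
    )
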
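"""Boolean genotype-phenotype maps: gene-network and linear chromosomes.

A quantitative trait is encoded either by a single-input Boolean gene network
(a directed acyclic graph in which every gene except the root is regulated by
exactly one upstream gene) or by a purely additive Boolean string.  The
network chromosome stores, for each gene ``i >= 1``, the index of its
regulator (the "head") and a function bit (1 = activator, 0 = repressor);
gene 0 carries a heritable root state instead.  Gene states propagate down
the network by an XNOR rule — a gene is on exactly when its regulator's state
matches the regulatory function — and the phenotype is the on-fraction of the
*terminal* genes (out-degree zero) scaled to the environmental range.

Acyclicity is structural: the head of gene ``i`` is always drawn from
``{0..i-1}``, so no sequence of mutation or recombination events can create a
feedback loop.

Two implementation routes coexist deliberately: plain per-chromosome
reference operators (this module's public scalar API) and vectorised batch
kernels (``*_batch``) used by the population engine.  Tests hold the two
routes to the same semantics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "InvalidParameterError",
    "IncompatibleParentsError",
    "GeneBlock",
    "NetworkChromosome",
    "LinearChromosome",
    "TOPOLOGIES",
    "build_network",
    "build_networks_batch",
    "propagate_states",
    "propagate_states_batch",
    "terminal_mask",
    "terminal_mask_batch",
    "phenotype_network",
    "phenotype_network_batch",
    "phenotype_linear",
    "phenotype_linear_batch",
    "mutate",
    "mutate_network_batch",
    "mutate_linear_batch",
    "recombine",
    "recombine_network_batch",
    "recombine_linear_batch",
    "to_networkx",
    "write_graphml",
    "write_dot",
    "chromosome_to_json",
    "chromosome_from_json",
]

ENV_RANGE = 140.0  #: default trait scale: the range of environmental values

TOPOLOGIES = ("random", "scale_free")

Topology = Literal["random", "scale_free"]


class InvalidParameterError(ValueError):
    """A parameter is outside its valid domain."""


class IncompatibleParentsError(ValueError):
    """Parents differ in size or architecture class and cannot recombine."""


@dataclass(frozen=True)
class GeneBlock:
    """One heritable gene block: regulator index plus function bit."""

    head: int
    function: int  # 1 = activator, 0 = repressor


@dataclass
class NetworkChromosome:
    """Single-input Boolean network genotype.

    Parameters
    ----------
    heads
        Integer array of length ``n - 1``; ``heads[i - 1]`` is the regulator
        of gene ``i`` and must satisfy ``heads[i - 1] < i``.
    functions
        Bit array of length ``n - 1``; 1 = activator, 0 = repressor.
    root_state
        Heritable state bit of gene 0 (the only unregulated gene).

    The mutational target comprises ``2n - 1`` elements: ``n - 1`` heads,
    ``n - 1`` function bits, and the root state.
    """

    heads: np.ndarray
    functions: np.ndarray
    root_state: int

    def __post_init__(self) -> None:
        self.heads = np.asarray(self.heads, dtype=np.int64)
        self.functions = np.asarray(self.functions, dtype=np.int8)
        n = self.heads.size + 1
        if n < 2:
            raise InvalidParameterError("network chromosome requires n >= 2")
        if self.functions.size != self.heads.size:
            raise InvalidParameterError("heads and functions length mismatch")
        idx = np.arange(1, n)
        if np.any(self.heads < 0) or np.any(self.heads >= idx):
            raise InvalidParameterError("head(i) must lie in {0..i-1}")
        if not np.isin(self.functions, (0, 1)).all():
            raise InvalidParameterError("function bits must be 0 or 1")
        if self.root_state not in (0, 1):
            raise InvalidParameterError("root_state must be 0 or 1")

    @property
    def n(self) -> int:
        """Number of genes."""
        return self.heads.size + 1

    @property
    def n_mutable(self) -> int:
        """Size of the mutational target (2n - 1)."""
        return 2 * self.n - 1

    @property
    def blocks(self) -> list[GeneBlock]:
        return [GeneBlock(int(h), int(f)) for h, f in zip(self.heads, self.functions)]

    def copy(self) -> "NetworkChromosome":
        return NetworkChromosome(self.heads.copy(), self.functions.copy(), self.root_state)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkChromosome):
            return NotImplemented
        return (
            self.root_state == other.root_state
            and np.array_equal(self.heads, other.heads)
            and np.array_equal(self.functions, other.functions)
        )


@dataclass
class LinearChromosome:
    """Purely additive Boolean genotype: an ordered string of ``n`` loci."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.size < 1:
            raise InvalidParameterError("linear chromosome requires n >= 1")
        if not np.isin(self.bits, (0, 1)).all():
            raise InvalidParameterError("alleles must be 0 or 1")

    @property
    def n(self) -> int:
        return self.bits.size

    @property
    def n_mutable(self) -> int:
        return self.bits.size

    def copy(self) -> "LinearChromosome":
        return LinearChromosome(self.bits.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinearChromosome):
            return NotImplemented
        return np.array_equal(self.bits, other.bits)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_networks_batch(
    n: int, topology: Topology, m: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate ``m`` random network chromosomes of ``n`` genes.

    Genes are added sequentially.  Under ``random`` topology the regulator of
    gene ``i`` is uniform on ``{0..i-1}``; under ``scale_free`` it is drawn
    by lottery with probability proportional to (current out-degree + 1), the
    +1 smoothing making degree-zero genes eligible for their first edge.
    Function bits and root states are fair coin flips.

    Returns ``(heads, functions, root_states)`` with shapes
    ``(m, n-1), (m, n-1), (m,)``.
    """
    if n < 2:
        raise InvalidParameterError("network requires n >= 2 genes")
    if topology not in TOPOLOGIES:
        raise InvalidParameterError(f"unknown topology {topology!r}")
    heads = np.zeros((m, n - 1), dtype=np.int64)
    if topology == "random":
        for i in range(2, n):
            heads[:, i - 1] = rng.integers(0, i, size=m)
    else:
        outdeg = np.zeros((m, n), dtype=np.int64)
        outdeg[:, 0] = 1  # gene 1 necessarily attaches to gene 0
        for i in range(2, n):
            weights = outdeg[:, :i] + 1
            cum = np.cumsum(weights, axis=1)
            u = rng.random(m) * cum[:, -1]
            choice = (u[:, None] >= cum).sum(axis=1)
            heads[:, i - 1] = choice
            outdeg[np.arange(m), choice] += 1
    functions = rng.integers(0, 2, size=(m, n - 1), dtype=np.int8)
    roots = rng.integers(0, 2, size=m, dtype=np.int8)
    return heads, functions, roots


def build_network(n: int, topology: Topology, rng: np.random.Generator) -> NetworkChromosome:
    """Generate one random network chromosome (see :func:`build_networks_batch`)."""
    heads, funcs, roots = build_networks_batch(n, topology, 1, rng)
    return NetworkChromosome(heads[0], funcs[0], int(roots[0]))


# ---------------------------------------------------------------------------
# state propagation and phenotype
# ---------------------------------------------------------------------------

def propagate_states(chrom: NetworkChromosome) -> np.ndarray:
    """Compute gene states by the XNOR rule, in index order.

    ``state(i) = 1`` iff the regulator's state equals the function bit: an
    "on" activator or an "off" repressor switches its target on; an "off"
    activator or an "on" repressor switches it off.
    """
    n = chrom.n
    states = np.empty(n, dtype=np.int8)
    states[0] = chrom.root_state
    heads = chrom.heads
    funcs = chrom.functions
    for i in range(1, n):
        states[i] = 1 if states[heads[i - 1]] == funcs[i - 1] else 0
    return states


def propagate_states_batch(
    heads: np.ndarray, functions: np.ndarray, root_states: np.ndarray
) -> np.ndarray:
    """Vectorised state propagation across a population (rows)."""
    m, nm1 = heads.shape
    states = np.empty((m, nm1 + 1), dtype=np.int8)
    states[:, 0] = root_states
    rows = np.arange(m)
    for i in range(1, nm1 + 1):
        states[:, i] = states[rows, heads[:, i - 1]] == functions[:, i - 1]
    return states


def terminal_mask(chrom: NetworkChromosome) -> np.ndarray:
    """Boolean mask of terminal genes (out-degree zero)."""
    outdeg = np.bincount(chrom.heads, minlength=chrom.n)
    return outdeg == 0


def terminal_mask_batch(heads: np.ndarray) -> np.ndarray:
    """Per-row terminal-gene masks for a population of networks."""
    m, nm1 = heads.shape
    n = nm1 + 1
    flat = heads + n * np.arange(m)[:, None]
    outdeg = np.bincount(flat.ravel(), minlength=m * n).reshape(m, n)
    return outdeg == 0


def phenotype_network(chrom: NetworkChromosome, env_range: float = ENV_RANGE) -> float:
    """Trait value: on-fraction of terminal genes scaled to ``env_range``.

    With ``T`` terminal genes of which ``T_on`` are on, the phenotype is
    ``(env_range / T) * T_on`` — e.g. 8 terminals with 4 on gives 70 on the
    default scale of 140.  Smaller networks therefore resolve the trait more
    coarsely than larger ones.
    """
    states = propagate_states(chrom)
    term = terminal_mask(chrom)
    t = int(term.sum())
    return env_range / t * int(states[term].sum())


def phenotype_network_batch(
    heads: np.ndarray, functions: np.ndarray, root_states: np.ndarray,
    env_range: float = ENV_RANGE,
) -> np.ndarray:
    states = propagate_states_batch(heads, functions, root_states)
    term = terminal_mask_batch(heads)
    t = term.sum(axis=1)
    t_on = (states * term).sum(axis=1)
    return env_range / t * t_on


def phenotype_linear(chrom: LinearChromosome, env_range: float = ENV_RANGE) -> float:
    """Additive trait value: sum of loci scaled to ``env_range``."""
    return env_range / chrom.n * int(chrom.bits.sum())


def phenotype_linear_batch(bits: np.ndarray, env_range: float = ENV_RANGE) -> np.ndarray:
    return env_range / bits.shape[1] * bits.sum(axis=1)


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

def _check_rate(x: float, name: str) -> None:
    if not 0.0 <= x <= 1.0:
        raise InvalidParameterError(f"{name} must lie in [0, 1], got {x}")


def mutate(
    chrom: NetworkChromosome | LinearChromosome,
    mu: float,
    rng: np.random.Generator,
) -> NetworkChromosome | LinearChromosome:
    """Return a mutated copy; each mutable element mutates independently.

    Network chromosomes expose ``2n - 1`` mutable elements.  A function-bit
    mutation flips activator and repressor; a head mutation redraws the
    regulator uniformly from the lower-index genes *excluding* the current
    one (so a mutation always changes the genotype — gene 1, whose only
    possible regulator is gene 0, is the single immutable head); a root-state
    mutation flips the bit.  Linear chromosomes flip each of their ``n`` loci
    independently (callers model the network's larger target by doubling
    ``mu``).
    """
    _check_rate(mu, "mutation rate")
    if isinstance(chrom, LinearChromosome):
        out = chrom.copy()
        flip = rng.random(out.n) < mu
        out.bits[flip] ^= 1
        return out
    out = chrom.copy()
    if rng.random() < mu:
        out.root_state ^= 1
    for i in range(1, out.n):
        if rng.random() < mu and i >= 2:
            u = int(rng.integers(0, i - 1))
            out.heads[i - 1] = u + (u >= out.heads[i - 1])
    flip = rng.random(out.n - 1) < mu
    out.functions[flip] ^= 1
    return out


def mutate_network_batch(
    heads: np.ndarray,
    functions: np.ndarray,
    root_states: np.ndarray,
    mu: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-element mutation of a population of networks (copies)."""
    _check_rate(mu, "mutation rate")
    m, nm1 = heads.shape
    heads = heads.copy()
    functions = functions.copy()
    root_states = root_states.copy()

    root_states[rng.random(m) < mu] ^= 1
    functions[rng.random((m, nm1)) < mu] ^= 1

    head_mask = rng.random((m, nm1)) < mu
    head_mask[:, 0] = False  # gene 1 has no alternative regulator
    rr, cc = np.nonzero(head_mask)
    if rr.size:
        i = cc + 1  # gene index of each mutating head
        u = np.floor(rng.random(rr.size) * (i - 1)).astype(np.int64)
        cur = heads[rr, cc]
        heads[rr, cc] = u + (u >= cur)
    return heads, functions, root_states


def mutate_linear_batch(
    bits: np.ndarray, mu: float, rng: np.random.Generator
) -> np.ndarray:
    _check_rate(mu, "mutation rate")
    bits = bits.copy()
    bits[rng.random(bits.shape) < mu] ^= 1
    return bits


# ---------------------------------------------------------------------------
# recombination
# ---------------------------------------------------------------------------

def recombine(
    parent_a: NetworkChromosome | LinearChromosome,
    parent_b: NetworkChromosome | LinearChromosome,
    r: float,
    rng: np.random.Generator,
) -> NetworkChromosome | LinearChromosome:
    """Recombine two parents into one offspring chromosome.

    The first element is copied from a fair-coin starting parent; at each
    subsequent element boundary a switch to the opposite parent occurs with
    probability ``r``.  The unit of exchange is the whole gene block (head
    and function move together; element 0 is the root state) for networks,
    and the single locus for linear chromosomes.  Because both parents
    satisfy ``head(i) < i``, the offspring does too.
    """
    _check_rate(r, "recombination rate")
    if type(parent_a) is not type(parent_b) or parent_a.n != parent_b.n:
        raise IncompatibleParentsError(
            "parents must share architecture class and size"
        )
    parents = (parent_a, parent_b)
    cur = int(rng.integers(0, 2))
    if isinstance(parent_a, LinearChromosome):
        bits = np.empty(parent_a.n, dtype=np.int8)
        bits[0] = parents[cur].bits[0]
        for i in range(1, parent_a.n):
            if rng.random() < r:
                cur = 1 - cur
            bits[i] = parents[cur].bits[i]
        return LinearChromosome(bits)
    n = parent_a.n
    heads = np.empty(n - 1, dtype=np.int64)
    funcs = np.empty(n - 1, dtype=np.int8)
    root = parents[cur].root_state
    for i in range(1, n):
        if rng.random() < r:
            cur = 1 - cur
        heads[i - 1] = parents[cur].heads[i - 1]
        funcs[i - 1] = parents[cur].functions[i - 1]
    return NetworkChromosome(heads, funcs, root)


def _crossover_masks(
    n_elements: int, m: int, r: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-offspring boolean matrix: True where the element comes from parent B."""
    start = rng.integers(0, 2, size=m, dtype=np.int8)
    switches = (rng.random((m, n_elements - 1)) < r).astype(np.int8)
    parity = np.cumsum(switches, axis=1) & 1
    take_b = np.empty((m, n_elements), dtype=bool)
    take_b[:, 0] = start == 1
    take_b[:, 1:] = (start[:, None] ^ parity) == 1
    return take_b


def recombine_network_batch(
    heads: np.ndarray,
    functions: np.ndarray,
    root_states: np.ndarray,
    mom: np.ndarray,
    dad: np.ndarray,
    r: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised block-wise recombination.

    ``mom``/``dad`` are per-offspring row indices into the parental arrays.
    Element 0 is the root state; elements 1..n-1 are whole gene blocks.
    """
    _check_rate(r, "recombination rate")
    n = heads.shape[1] + 1
    m = mom.size
    take_b = _crossover_masks(n, m, r, rng)
    src = np.where(take_b, dad[:, None], mom[:, None])
    off_root = root_states[src[:, 0]]
    cols = np.arange(n - 1)
    off_heads = heads[src[:, 1:], cols]
    off_funcs = functions[src[:, 1:], cols]
    return off_heads, off_funcs, off_root


def recombine_linear_batch(
    bits: np.ndarray,
    mom: np.ndarray,
    dad: np.ndarray,
    r: float,
    rng: np.random.Generator,
) -> np.ndarray:
    _check_rate(r, "recombination rate")
    n = bits.shape[1]
    take_b = _crossover_masks(n, mom.size, r, rng)
    src = np.where(take_b, dad[:, None], mom[:, None])
    return bits[src, np.arange(n)]


# ---------------------------------------------------------------------------
# inspection and serialization
# ---------------------------------------------------------------------------

def to_networkx(chrom: NetworkChromosome):
    """Export as a :class:`networkx.DiGraph` annotated with states and roles."""
    import networkx as nx

    states = propagate_states(chrom)
    term = terminal_mask(chrom)
    g = nx.DiGraph()
    for i in range(chrom.n):
        g.add_node(i, state=int(states[i]), terminal=bool(term[i]))
    for i in range(1, chrom.n):
        kind = "activator" if chrom.functions[i - 1] == 1 else "repressor"
        g.add_edge(int(chrom.heads[i - 1]), i, function=kind)
    return g


def write_graphml(chrom: NetworkChromosome, path: str) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(chrom), path)


def write_dot(chrom: NetworkChromosome, path: str) -> None:
    """Write a GraphViz DOT rendering (filled = on, box = terminal)."""
    states = propagate_states(chrom)
    term = terminal_mask(chrom)
    lines = ["digraph gene_network {"]
    for i in range(chrom.n):
        shape = "box" if term[i] else "ellipse"
        fill = "black" if states[i] else "white"
        fontcolor = "white" if states[i] else "black"
        lines.append(
            f'  g{i} [shape={shape}, style=filled, fillcolor={fill}, '
            f'fontcolor={fontcolor}, label="{i}"];'
        )
    for i in range(1, chrom.n):
        style = "solid" if chrom.functions[i - 1] == 1 else "dashed"
        lines.append(f"  g{int(chrom.heads[i - 1])} -> g{i} [style={style}];")
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def chromosome_to_json(chrom: NetworkChromosome | LinearChromosome) -> str:
    if isinstance(chrom, LinearChromosome):
        payload = {"architecture": "linear", "n": chrom.n, "bits": chrom.bits.tolist()}
    else:
        payload = {
            "architecture": "network",
            "n": chrom.n,
            "heads": chrom.heads.tolist(),
            "functions": chrom.functions.tolist(),
            "root_state": int(chrom.root_state),
        }
    return json.dumps(payload)


def chromosome_from_json(text: str) -> NetworkChromosome | LinearChromosome:
    payload = json.loads(text)
    if payload["architecture"] == "linear":
        return LinearChromosome(np.asarray(payload["bits"]))
    return NetworkChromosome(
        np.asarray(payload["heads"]),
        np.asarray(payload["functions"]),
        int(payload["root_state"]),
    )
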
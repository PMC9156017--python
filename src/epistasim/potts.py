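"""Potts Hamiltonian model over aligned protein-domain positions.

The model assigns every length-``N`` sequence ``a`` an unnormalised log
probability (statistical "Hamiltonian" energy)

    E(a) = sum_{i<j} J_ij(a_i, a_j) + sum_i h_i(a_i),

where ``J`` holds pairwise residue couplings between sites and ``h`` holds
local single-site residue preferences ("fields").  The state space at every
site has 21 characters: the 20 amino acids plus the alignment gap ``-``,
which is treated as an ordinary 21st state throughout.

Three nested evolutionary regimes are derived from one parameter set:

* **CE** (coupled evolution): both ``J`` and ``h`` active;
* **IE** (independent evolution): ``J`` forced to zero, ``h`` active;
* **UE** (uniform evolution): both zero — the strictly neutral null in
  which every character is equally likely at every step.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PROTEIN_GAP_ALPHABET",
    "Alphabet",
    "EvolutionMode",
    "PottsModel",
    "hamiltonian_log_weight",
    "conditional_distribution",
    "nest_model",
    "frobenius_coupling_map",
]

#: Fixed state ordering used by synthetic models: the 20 amino acids in
#: alphabetical one-letter order followed by the alignment gap.
PROTEIN_GAP_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"

_SYMMETRY_WARN_TOL = 1e-8


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet mapping symbols to state indices 0..q-1."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")

    @classmethod
    def protein_gap(cls) -> "Alphabet":
        """The canonical 21-state alphabet (20 amino acids + '-' gap)."""
        return cls(tuple(PROTEIN_GAP_ALPHABET))

    @classmethod
    def generic(cls, n_states: int) -> "Alphabet":
        """A small abstract alphabet ('0', '1', ...) for reduced-state models."""
        if n_states == 21:
            return cls.protein_gap()
        return cls(tuple(str(i) for i in range(n_states)))

    @property
    def n_states(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def encode(self, sequence: str) -> np.ndarray:
        """Translate a string of symbols into a state-index vector."""
        lookup = {s: i for i, s in enumerate(self.symbols)}
        return np.array([lookup[c] for c in sequence], dtype=np.int8)

    def decode(self, states: np.ndarray) -> str:
        return "".join(self.symbols[int(s)] for s in states)


class EvolutionMode(enum.Enum):
    """Nested evolutionary regimes: CE ⊃ IE ⊃ UE."""

    CE = "CE"
    IE = "IE"
    UE = "UE"


@dataclass
class PottsModel:
    """Couplings ``J`` (N,N,q,q), fields ``h`` (N,q) and optional native sequence.

    ``couplings[i, j, a, b]`` is J_ij(a, b); the full symmetric tensor is
    stored with both (i, j) and (j, i) blocks populated so that the
    single-site conditional can sum over all partners without triangular
    bookkeeping.  The symmetry contract J_ij(a,b) == J_ji(b,a) and a zero
    diagonal block J_ii ≡ 0 are enforced by :meth:`validate` /
    :meth:`from_arrays`.
    """

    couplings: np.ndarray
    fields: np.ndarray
    alphabet: Alphabet = field(default_factory=Alphabet.protein_gap)
    native_sequence: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return self.fields.shape[0]

    @property
    def n_states(self) -> int:
        return self.fields.shape[1]

    def __post_init__(self) -> None:
        self.couplings = np.ascontiguousarray(self.couplings, dtype=np.float64)
        self.fields = np.ascontiguousarray(self.fields, dtype=np.float64)
        if self.native_sequence is not None:
            self.native_sequence = np.asarray(self.native_sequence, dtype=np.int8)

    @classmethod
    def from_arrays(
        cls,
        couplings: np.ndarray,
        fields: np.ndarray,
        alphabet: Alphabet | None = None,
        native_sequence: np.ndarray | None = None,
    ) -> "PottsModel":
        """Build a model, symmetrising J and zeroing its diagonal blocks.

        Asymmetry between J_ij(a,b) and J_ji(b,a) beyond 1e-8 triggers a
        warning; the average of the two is kept either way.
        """
        couplings = np.asarray(couplings, dtype=np.float64)
        fields = np.asarray(fields, dtype=np.float64)
        n, q = fields.shape
        if couplings.shape != (n, n, q, q):
            raise ValueError(
                f"couplings shape {couplings.shape} incompatible with fields {fields.shape}"
            )
        mirrored = couplings.transpose(1, 0, 3, 2)
        asym = np.max(np.abs(couplings - mirrored)) if n > 1 else 0.0
        if asym > _SYMMETRY_WARN_TOL:
            warnings.warn(
                f"coupling tensor asymmetry {asym:.3g} exceeds {_SYMMETRY_WARN_TOL:g}; symmetrising",
                stacklevel=2,
            )
        couplings = 0.5 * (couplings + mirrored)
        couplings[np.arange(n), np.arange(n)] = 0.0
        if alphabet is None:
            alphabet = Alphabet.generic(q)
        model = cls(couplings, fields, alphabet, native_sequence)
        model.validate()
        return model

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        n, q = self.fields.shape
        if self.couplings.shape != (n, n, q, q):
            raise ValueError("couplings/fields dimension mismatch")
        if self.alphabet.n_states != q:
            raise ValueError("alphabet size does not match number of states")
        if not (np.isfinite(self.couplings).all() and np.isfinite(self.fields).all()):
            raise ValueError("non-finite model parameters")
        if np.max(np.abs(self.couplings - self.couplings.transpose(1, 0, 3, 2))) > 1e-10:
            raise ValueError("coupling tensor violates J_ij(a,b) == J_ji(b,a)")
        if np.max(np.abs(self.couplings[np.arange(n), np.arange(n)])) != 0.0:
            raise ValueError("self-couplings J_ii must be zero")
        if self.native_sequence is not None:
            seq = self.native_sequence
            if seq.shape != (n,) or seq.min() < 0 or seq.max() >= q:
                raise ValueError("native sequence incompatible with model dimensions")

    def nested(self, mode: EvolutionMode) -> "PottsModel":
        return nest_model(self, mode)


def _check_sequence(seq: np.ndarray, model: PottsModel) -> np.ndarray:
    seq = np.asarray(seq)
    if seq.shape != (model.n_sites,):
        raise ValueError(
            f"sequence length {seq.shape} does not match model with N={model.n_sites}"
        )
    return seq.astype(np.intp)


def hamiltonian_log_weight(seq: np.ndarray, model: PottsModel) -> float:
    """Log of the unnormalised Potts probability of ``seq``.

    Returns sum_{i<j} J_ij(a_i, a_j) + sum_i h_i(a_i).  The partition
    function Z is never computed; ratios/differences of this quantity are
    what the Gibbs sampler uses.
    """
    s = _check_sequence(seq, model)
    n = model.n_sites
    sites = np.arange(n)
    # pair term: full matrix of J_ij(a_i, a_j), halved because J is symmetric
    pair = model.couplings[sites[:, None], sites[None, :], s[:, None], s[None, :]]
    return float(0.5 * pair.sum() + model.fields[sites, s].sum())


def conditional_log_weights(
    seq: np.ndarray, site: int, model: PottsModel, mode: EvolutionMode = EvolutionMode.CE
) -> np.ndarray:
    """Unnormalised log conditional weights of the q states at ``site``.

    CE: h_site(a) + sum_{j != site} J_site,j(a, seq_j); IE: h_site(a);
    UE: all zeros (uniform).
    """
    s = _check_sequence(seq, model)
    n, q = model.n_sites, model.n_states
    if not 0 <= site < n:
        raise IndexError(f"site {site} out of range for N={n}")
    if mode is EvolutionMode.UE:
        return np.zeros(q)
    logits = model.fields[site].copy()
    if mode is EvolutionMode.CE:
        # couplings[site, j, :, seq_j] summed over all partners j != site
        contrib = model.couplings[site, np.arange(n), :, s]  # (n, q)
        contrib[site] = 0.0
        logits += contrib.sum(axis=0)
    return logits


def conditional_distribution(
    seq: np.ndarray, site: int, model: PottsModel, mode: EvolutionMode = EvolutionMode.CE
) -> np.ndarray:
    """Gibbs single-site conditional P(a_site = a | rest of sequence).

    Computed in log space with max-subtraction for numerical stability.
    Under UE this is exactly the uniform distribution 1/q.
    """
    logits = conditional_log_weights(seq, site, model, mode)
    w = np.exp(logits - logits.max())
    return w / w.sum()


def nest_model(model: PottsModel, mode: EvolutionMode) -> PottsModel:
    """Return the model with parameters zeroed according to the nesting.

    CE returns the model unchanged (same object); IE zeroes J; UE zeroes
    J and h.
    """
    if mode is EvolutionMode.CE:
        return model
    zero_j = np.zeros_like(model.couplings)
    if mode is EvolutionMode.IE:
        return replace(model, couplings=zero_j, fields=model.fields.copy())
    return replace(model, couplings=zero_j, fields=np.zeros_like(model.fields))


def frobenius_coupling_map(model: PottsModel) -> np.ndarray:
    """N×N matrix of Frobenius norms of each 21×21 coupling block.

    Entry (i, j) = sqrt(sum_ab J_ij(a,b)^2); symmetric with a zero
    diagonal.  This is the standard site-pair coupling-strength summary
    used to visualise which positions interact.
    """
    return np.sqrt(np.einsum("ijab,ijab->ij", model.couplings, model.couplings))
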
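"""Reading and writing model parameters, sequences and traces.

Two parameter sources are supported: MATLAB ``Parameters_orig``-style
files holding the coupling tensor, field matrix and annotated native
sequence of a domain family (both the classic MAT dialect via
scipy.io and the v7.3/HDF5 dialect via h5py), and this package's own
portable HDF5 container with an embedded JSON header.  Because MAT files
do not document their axis order, the loader identifies the state axes
by size (q=21) and normalises whatever layout it finds to
(N, N, q, q) / (N, q), recording what it detected in the model metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .potts import Alphabet, PottsModel
from .simulate import EvolutionTrace

__all__ = [
    "load_mat_parameters",
    "save_model",
    "load_model",
    "write_fasta",
    "write_trace_tsv",
    "read_trace_tsv",
]

_J_KEYS = ("J", "couplings", "Jij", "J_ij", "eij")
_H_KEYS = ("h", "fields", "hi", "h_i")
_SEQ_KEYS = ("native", "native_sequence", "seq", "sequence", "refseq", "wt_seq")


def _normalize_couplings(arr: np.ndarray, q: int = 21) -> np.ndarray:
    """Reorder a 4-D coupling array to (site, site, state, state)."""
    if arr.ndim != 4:
        raise ValueError(f"expected 4-D coupling array, got shape {arr.shape}")
    state_axes = [ax for ax, s in enumerate(arr.shape) if s == q]
    site_axes = [ax for ax in range(4) if ax not in state_axes[:2]]
    if len(state_axes) < 2:
        raise ValueError(f"could not find two state axes of size {q} in shape {arr.shape}")
    state_axes = state_axes[:2]
    if arr.shape[site_axes[0]] != arr.shape[site_axes[1]]:
        raise ValueError(f"site axes differ in length in shape {arr.shape}")
    return np.ascontiguousarray(arr.transpose(site_axes[0], site_axes[1], state_axes[0], state_axes[1]))


def _normalize_fields(arr: np.ndarray, n: int, q: int = 21) -> np.ndarray:
    arr = np.squeeze(arr)
    if arr.shape == (n, q):
        return np.ascontiguousarray(arr)
    if arr.shape == (q, n):
        return np.ascontiguousarray(arr.T)
    raise ValueError(f"field array shape {arr.shape} incompatible with N={n}, q={q}")


def _coerce_native(value, n: int, q: int, alphabet: Alphabet) -> np.ndarray | None:
    if value is None:
        return None
    arr = np.squeeze(np.asarray(value))
    if arr.dtype.kind in "US" or arr.dtype.kind == "O":
        text = "".join(np.atleast_1d(arr).astype(str))
        return alphabet.encode(text)
    arr = arr.astype(np.int64).ravel()
    if len(arr) != n:
        return None
    if arr.min() >= 1 and arr.max() <= q:
        arr = arr - 1  # MATLAB 1-based state indices
    return arr.astype(np.int8)


def _pick_key(keys, candidates, ndim_of, want_ndim):
    named = [k for k in keys if k.lower() in candidates]
    if named:
        return named[0]
    by_shape = [k for k in keys if ndim_of(k) == want_ndim]
    if len(by_shape) == 1:
        return by_shape[0]
    raise KeyError(f"cannot identify a unique {want_ndim}-D parameter array among {sorted(keys)}")


def load_mat_parameters(path: str | Path, q: int = 21) -> PottsModel:
    """Load a Potts model from a MATLAB parameter file (classic or v7.3)."""
    path = Path(path)
    try:
        from scipy.io import loadmat

        raw = loadmat(path)
        data = {k: np.asarray(v) for k, v in raw.items() if not k.startswith("__")}
    except (ValueError, NotImplementedError):  # v7.3 files are HDF5
        data = {}
        with h5py.File(path, "r") as f:
            def visit(name, obj):
                if isinstance(obj, h5py.Dataset):
                    data[name.split("/")[-1]] = obj[()]

            f.visititems(visit)
    ndim_of = lambda k: np.squeeze(data[k]).ndim
    j_key = _pick_key(data, _J_KEYS, ndim_of, 4)
    h_key = _pick_key(data, _H_KEYS, ndim_of, 2)
    couplings = _normalize_couplings(np.asarray(data[j_key], dtype=np.float64), q)
    n = couplings.shape[0]
    fields = _normalize_fields(np.asarray(data[h_key], dtype=np.float64), n, q)
    alphabet = Alphabet.protein_gap() if q == 21 else Alphabet.generic(q)
    native = None
    for key in data:
        if key.lower() in _SEQ_KEYS:
            native = _coerce_native(data[key], n, q, alphabet)
            break
    return PottsModel.from_arrays(couplings, fields, alphabet, native)


def save_model(model: PottsModel, path: str | Path) -> None:
    """Write the portable HDF5 container with a JSON header."""
    header = {
        "format": "epistasim-potts-model",
        "version": 1,
        "n_sites": model.n_sites,
        "n_states": model.n_states,
        "alphabet": "".join(model.alphabet.symbols),
    }
    with h5py.File(path, "w") as f:
        f.attrs["header"] = json.dumps(header)
        f.create_dataset("couplings", data=model.couplings, compression="gzip")
        f.create_dataset("fields", data=model.fields, compression="gzip")
        if model.native_sequence is not None:
            f.create_dataset("native_sequence", data=model.native_sequence)


def load_model(path: str | Path) -> PottsModel:
    """Read a model written by :func:`save_model`."""
    with h5py.File(path, "r") as f:
        header = json.loads(f.attrs["header"])
        couplings = f["couplings"][()]
        fields = f["fields"][()]
        native = f["native_sequence"][()] if "native_sequence" in f else None
    alphabet = Alphabet(tuple(header["alphabet"]))
    return PottsModel.from_arrays(couplings, fields, alphabet, native)


def write_fasta(sequences: dict[str, np.ndarray], alphabet: Alphabet, path: str | Path) -> None:
    """Write state-index sequences as FASTA via their alphabet symbols."""
    records = [
        SeqRecord(Seq(alphabet.decode(states)), id=name, description="")
        for name, states in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_trace_tsv(trace: EvolutionTrace, path: str | Path) -> None:
    """Write one trace as TSV with '#'-prefixed header metadata lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# mode={trace.mode.value}\n")
        fh.write(f"# n_sites={trace.n_sites}\n")
        fh.write(f"# replicate_id={trace.replicate_id}\n")
        fh.write(f"# reference_sequence={','.join(map(str, trace.reference_sequence))}\n")
        fh.write("generation\tsite\tresidue_before\tresidue_proposed\taccepted\n")
        for g in range(trace.n_tracked):
            fh.write(
                f"{g + 1}\t{trace.sites[g]}\t{trace.residues_before[g]}"
                f"\t{trace.residues_proposed[g]}\t{int(trace.accepted[g])}\n"
            )


def read_trace_tsv(path: str | Path) -> EvolutionTrace:
    """Read a trace written by :func:`write_trace_tsv`."""
    from .potts import EvolutionMode

    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
            pos = fh.tell()
            line = fh.readline()
    body = np.loadtxt(path, skiprows=len(meta) + 1, dtype=np.int64, ndmin=2)
    ref = np.array([int(x) for x in meta["reference_sequence"].split(",")], dtype=np.int8)
    trace = EvolutionTrace(
        mode=EvolutionMode(meta["mode"]),
        n_sites=int(meta["n_sites"]),
        reference_sequence=ref,
        sites=body[:, 1].astype(np.int32),
        residues_before=body[:, 2].astype(np.int8),
        residues_proposed=body[:, 3].astype(np.int8),
        accepted=body[:, 4].astype(bool),
        final_sequence=ref,  # replaced below
        replicate_id=int(meta["replicate_id"]),
    )
    trace.final_sequence = trace.replay()
    return trace
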
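"""Binary molecular fingerprints and Tanimoto (Jaccard) similarity.

A fingerprint is a fixed-length bit string (default 1024 bits, as for folded
circular/ECFP fingerprints).  Similarity between two molecules A and B is the
Tanimoto coefficient

    T(A, B) = N_A&B / (N_A + N_B - N_A&B)

where ``N_A`` and ``N_B`` count the set bits of each string and ``N_A&B`` the
bits set in both; the corresponding distance is ``D = 1 - T``, which is a
metric on bit strings.  The class-averaged distances of a query compound to a
panel of known binders and known non-binders (``avgD_Act``/``avgD_Inact``) are
the ligand-based descriptors used by the consensus classifiers.

Bits are stored packed (one byte per 8 bits); popcounts use the CPU popcount
via :func:`numpy.bitwise_count`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Fingerprint",
    "ReferencePanel",
    "tanimoto",
    "distance",
    "avg_distance",
    "smiles_to_ecfp",
    "pack_bit_matrix",
    "average_distance_matrix",
]


class Fingerprint:
    """Fixed-length binary fingerprint stored as a packed bit array.

    Parameters
    ----------
    bits : str or sequence of {0, 1}
        Either a text bit string (``"0101..."``) or an iterable of 0/1 values.
    """

    __slots__ = ("length", "_packed", "n_set")

    def __init__(self, bits):
        if isinstance(bits, str):
            if set(bits) - {"0", "1"}:
                raise ValueError("bit string may contain only '0' and '1'")
            arr = np.frombuffer(bits.encode("ascii"), dtype=np.uint8) - ord("0")
        else:
            arr = np.asarray(bits)
            if arr.size and not np.isin(arr, (0, 1)).all():
                raise ValueError("fingerprint bits must be 0 or 1")
            arr = arr.astype(np.uint8)
        if arr.ndim != 1:
            raise ValueError("fingerprint bits must be one-dimensional")
        if arr.size == 0:
            raise ValueError("fingerprint must have at least one bit")
        self.length = int(arr.size)
        self._packed = np.packbits(arr)
        self.n_set = int(np.bitwise_count(self._packed).sum())

    @classmethod
    def from_hex(cls, hexstring: str, length: int) -> "Fingerprint":
        """Decode a hex-encoded fingerprint of ``length`` bits."""
        if length <= 0 or length > 4 * len(hexstring):
            raise ValueError(
                f"cannot decode {length} bits from {len(hexstring)} hex characters"
            )
        raw = bytes.fromhex(hexstring)
        bits = np.unpackbits(np.frombuffer(raw, dtype=np.uint8))[:length]
        return cls(bits)

    @property
    def bits(self) -> np.ndarray:
        """Unpacked 0/1 array of length ``length``."""
        return np.unpackbits(self._packed)[: self.length]

    @property
    def packed(self) -> np.ndarray:
        return self._packed

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def to_hex(self) -> str:
        return self._packed.tobytes().hex()

    def __len__(self) -> int:
        return self.length

    def __eq__(self, other) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return self.length == other.length and np.array_equal(
            self._packed, other._packed
        )

    def __hash__(self) -> int:
        return hash((self.length, self._packed.tobytes()))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Fingerprint(length={self.length}, n_set={self.n_set})"


def _check_pair(a: Fingerprint, b: Fingerprint) -> None:
    if a.length != b.length:
        raise ValueError(
            f"fingerprint length mismatch: {a.length} vs {b.length}"
        )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) coefficient of two fingerprints, in [0, 1].

    Two all-zero fingerprints are treated as identical (coefficient 1), with
    a warning: the overlap ratio is 0/0 and "identically empty" is the
    convention adopted here.
    """
    _check_pair(a, b)
    inter = int(np.bitwise_count(a.packed & b.packed).sum())
    union = a.n_set + b.n_set - inter
    if union == 0:
        warnings.warn(
            "tanimoto of two all-zero fingerprints is undefined (0/0); "
            "returning 1.0 by the identical-emptiness convention",
            stacklevel=2,
        )
        return 1.0
    return inter / union


def distance(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) distance ``1 - T(a, b)``, a metric on bit strings."""
    return 1.0 - tanimoto(a, b)


def avg_distance(
    query: Fingerprint,
    panel_side: list,
    exclude_index: int | None = None,
) -> float:
    """Mean Tanimoto distance from ``query`` to one side of a reference panel.

    ``exclude_index`` implements leave-self-out: when the query is itself a
    member of the panel (training-set evaluation) its own entry is skipped,
    otherwise the average to its own class is biased low.
    """
    if exclude_index is not None and not 0 <= exclude_index < len(panel_side):
        raise IndexError(f"exclude_index {exclude_index} out of range")
    members = [
        fp for i, fp in enumerate(panel_side) if i != exclude_index
    ]
    if not members:
        raise ValueError("average distance over an empty panel is undefined")
    return float(np.mean([distance(query, fp) for fp in members]))


def pack_bit_matrix(fingerprints) -> tuple[np.ndarray, np.ndarray, int]:
    """Stack fingerprints into (packed matrix, per-row popcounts, length).

    Accepts a list of :class:`Fingerprint` or a 2-D 0/1 array (one row per
    molecule).
    """
    if isinstance(fingerprints, np.ndarray):
        if fingerprints.ndim != 2:
            raise ValueError("bit matrix must be 2-D")
        bits = fingerprints.astype(np.uint8)
        length = bits.shape[1]
        packed = np.packbits(bits, axis=1)
    else:
        fingerprints = list(fingerprints)
        if not fingerprints:
            raise ValueError("empty fingerprint list")
        lengths = {fp.length for fp in fingerprints}
        if len(lengths) > 1:
            raise ValueError(f"mixed fingerprint lengths in panel: {sorted(lengths)}")
        length = lengths.pop()
        packed = np.vstack([fp.packed for fp in fingerprints])
    counts = np.bitwise_count(packed).sum(axis=1).astype(np.int64)
    return packed, counts, length


def average_distance_matrix(
    query_packed: np.ndarray,
    query_counts: np.ndarray,
    panel_packed: np.ndarray,
    panel_counts: np.ndarray,
    exclude: np.ndarray | None = None,
    block: int = 256,
) -> np.ndarray:
    """Mean Tanimoto distance from each query row to a panel of fingerprints.

    ``exclude[i]`` is the panel row index occupied by query ``i`` itself
    (or -1); that member is left out of query ``i``'s average.  Pairs whose
    union of set bits is empty (both fingerprints all-zero) count as
    distance 0, matching the identical-emptiness convention of
    :func:`tanimoto`.
    """
    n_panel = panel_packed.shape[0]
    if n_panel == 0:
        raise ValueError("average distance over an empty panel is undefined")
    n_query = query_packed.shape[0]
    out = np.empty(n_query, dtype=float)
    for start in range(0, n_query, block):
        stop = min(start + block, n_query)
        q = query_packed[start:stop]
        inter = (
            np.bitwise_count(q[:, None, :] & panel_packed[None, :, :])
            .sum(axis=2)
            .astype(np.int64)
        )
        union = query_counts[start:stop, None] + panel_counts[None, :] - inter
        with np.errstate(invalid="ignore"):
            dist = 1.0 - inter / union
        dist[union == 0] = 0.0
        if exclude is None:
            out[start:stop] = dist.mean(axis=1)
        else:
            exc = exclude[start:stop]
            total = dist.sum(axis=1)
            has_self = exc >= 0
            self_d = np.zeros(stop - start)
            self_d[has_self] = dist[np.nonzero(has_self)[0], exc[has_self]]
            denom = np.where(has_self, n_panel - 1, n_panel)
            if np.any(denom == 0):
                raise ValueError("leave-self-out left an empty panel")
            out[start:stop] = (total - self_d) / denom
    return out


@dataclass
class ReferencePanel:
    """Known binders and non-binders used for average-distance descriptors."""

    actives: list = field(repr=False)
    inactives: list = field(repr=False)
    ids: list | None = None

    def __post_init__(self):
        if not self.actives or not self.inactives:
            raise ValueError("reference panel needs at least one fingerprint per class")
        self._act_packed, self._act_counts, len_a = pack_bit_matrix(self.actives)
        self._inact_packed, self._inact_counts, len_i = pack_bit_matrix(self.inactives)
        if len_a != len_i:
            raise ValueError("active and inactive fingerprints differ in length")
        self.length = len_a

    @classmethod
    def from_labels(cls, fingerprints, labels) -> "ReferencePanel":
        labels = np.asarray(labels)
        actives = [fp for fp, y in zip(fingerprints, labels) if y == 1]
        inactives = [fp for fp, y in zip(fingerprints, labels) if y == 0]
        return cls(actives=actives, inactives=inactives)

    @property
    def n_actives(self) -> int:
        return self._act_packed.shape[0]

    @property
    def n_inactives(self) -> int:
        return self._inact_packed.shape[0]

    def avg_distances(
        self,
        fingerprints,
        exclude_active: np.ndarray | None = None,
        exclude_inactive: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """(avgD_Act, avgD_Inact) per query fingerprint.

        The ``exclude_*`` arrays give, per query, the panel row occupied by
        the query itself (-1 when it is not a panel member); used for
        leave-self-out on the training set.
        """
        packed, counts, length = pack_bit_matrix(fingerprints)
        if length != self.length:
            raise ValueError(
                f"query fingerprint length {length} != panel length {self.length}"
            )
        d_act = average_distance_matrix(
            packed, counts, self._act_packed, self._act_counts, exclude_active
        )
        d_inact = average_distance_matrix(
            packed, counts, self._inact_packed, self._inact_counts, exclude_inactive
        )
        return d_act, d_inact


def smiles_to_ecfp(smiles: str, radius: int = 2, length: int = 1024) -> Fingerprint:
    """Circular (Morgan/ECFP-style) fingerprint from a SMILES string.

    Requires the optional RDKit dependency.  ``radius=2`` corresponds to the
    common ECFP4 setting; both radius and bit length are configurable because
    folded-fingerprint parameters are a modelling choice, not a constant.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "smiles_to_ecfp requires the optional dependency rdkit "
            "(pip install arclass[chem])"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=length)
    bv = gen.GetFingerprint(mol)
    bits = np.zeros(length, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits)
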
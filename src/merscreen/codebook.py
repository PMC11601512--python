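"""Constant-weight, error-robust binary codebooks for multiplexed FISH.

In MERFISH-style imaging, each RNA species (or perturbation barcode) is
assigned a binary codeword read out over sequential hybridization rounds.
Constant Hamming weight keeps the per-round signal density uniform, and a
minimum pairwise Hamming distance of 4 lets single-bit readout errors be
corrected: radius-1 spheres around codewords are disjoint, so any one-bit
corruption still identifies its source uniquely.

The generator here uses a position-sum-class construction: weight-``w``
words of length ``n`` are partitioned by the sum of their set-bit positions
modulo ``n``. Two distinct words in a class cannot differ by a single bit
move (that would change the sum by a nonzero amount mod ``n``), so their
distance is at least 4. The largest class alone guarantees at least
``floor(C(n, w) / n)`` codewords; greedy augmentation from the remaining
classes, in a seeded random order, then grows the code further.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Codeword",
    "Codebook",
    "DecodeCall",
    "CodeReport",
    "CodeInfeasibleError",
    "generate_constant_weight_code",
    "assign_targets",
    "schedule_rounds",
    "decode_bit_vector",
    "verify_code",
]


class CodeInfeasibleError(ValueError):
    """Raised when the search cannot reach the requested number of codewords.

    Carries ``best_count``, the largest code size achieved before giving up.
    """

    def __init__(self, message: str, best_count: int):
        super().__init__(message)
        self.best_count = best_count


@dataclass(frozen=True)
class Codeword:
    bits: tuple  # ordered 0/1 values, length n_bits
    index: int

    @property
    def weight(self) -> int:
        return int(sum(self.bits))

    @property
    def on_bits(self) -> tuple:
        return tuple(i for i, b in enumerate(self.bits) if b)

    def bit_string(self) -> str:
        return "".join(str(int(b)) for b in self.bits)


@dataclass
class Codebook:
    """A constant-weight codebook plus target assignment and round schedule.

    ``target_names`` maps codeword index -> target name for coding words;
    ``blank_flags`` marks codewords carrying no target, used downstream to
    estimate the misidentification rate. ``schedule`` maps bit -> (round,
    channel).
    """

    n_bits: int
    weight: int
    min_distance: int
    codewords: list = field(default_factory=list)
    target_names: dict = field(default_factory=dict)
    blank_flags: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)
    seed: int = 0

    def __len__(self) -> int:
        return len(self.codewords)

    @property
    def bit_matrix(self) -> np.ndarray:
        """(K, n_bits) uint8 matrix of codeword bits."""
        return np.array([cw.bits for cw in self.codewords], dtype=np.uint8)

    def name_of(self, index: int):
        return self.target_names.get(index)

    def is_blank(self, index: int) -> bool:
        return bool(self.blank_flags.get(index, False))

    @property
    def coding_indices(self) -> list:
        return sorted(self.target_names)

    @property
    def blank_indices(self) -> list:
        return sorted(i for i, b in self.blank_flags.items() if b)

    def used(self) -> "Codebook":
        """Sub-codebook restricted to named and blank codewords.

        Decoding in the pipeline runs against used codewords only, so that
        unassigned codewords cannot absorb calls.
        """
        keep = set(self.coding_indices) | set(self.blank_indices)
        if not keep:
            return self
        cws = [cw for cw in self.codewords if cw.index in keep]
        # reindex consecutively, remapping assignment dicts
        remap = {cw.index: i for i, cw in enumerate(cws)}
        new_cws = [replace(cw, index=remap[cw.index]) for cw in cws]
        return Codebook(
            n_bits=self.n_bits,
            weight=self.weight,
            min_distance=self.min_distance,
            codewords=new_cws,
            target_names={remap[i]: n for i, n in self.target_names.items()},
            blank_flags={remap[i]: b for i, b in self.blank_flags.items() if i in remap},
            schedule=dict(self.schedule),
            seed=self.seed,
        )

    # ---------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cw in self.codewords:
            rows.append(
                {
                    "name": self.target_names.get(cw.index, ""),
                    "id": cw.index,
                    "is_blank": int(self.is_blank(cw.index)),
                    "bit_string": cw.bit_string(),
                }
            )
        return pd.DataFrame(rows, columns=["name", "id", "is_blank", "bit_string"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, min_distance: int = 4, seed: int = 0) -> "Codebook":
        df = pd.read_csv(path, dtype={"bit_string": str})
        df["name"] = df["name"].fillna("")
        cws, names, blanks = [], {}, {}
        for _, row in df.iterrows():
            bits = tuple(int(c) for c in row["bit_string"])
            idx = int(row["id"])
            cws.append(Codeword(bits=bits, index=idx))
            if str(row["name"]):
                names[idx] = str(row["name"])
            blanks[idx] = bool(int(row["is_blank"]))
        n_bits = len(cws[0].bits)
        weight = cws[0].weight
        return cls(n_bits, weight, min_distance, cws, names, blanks, {}, seed)

    def schedule_to_frame(self) -> pd.DataFrame:
        rows = [
            {"bit": b, "round": r, "channel": c}
            for b, (r, c) in sorted(self.schedule.items())
        ]
        return pd.DataFrame(rows, columns=["bit", "round", "channel"])


@dataclass(frozen=True)
class DecodeCall:
    """Result of decoding one bit vector against a codebook."""

    outcome: str  # "target" | "blank" | "no_call"
    codeword_index: int | None
    hamming_distance: int
    corrected_bit: int | None = None
    target_name: str | None = None


@dataclass(frozen=True)
class CodeReport:
    size: int
    weights: frozenset
    min_distance: int | None  # None for a single-codeword code ("undefined")


def _pairwise_min_distance(bits: np.ndarray) -> int:
    """Exact minimum pairwise Hamming distance via overlap counting."""
    b = bits.astype(np.int32)
    w = b.sum(axis=1)
    overlap = b @ b.T
    dist = w[:, None] + w[None, :] - 2 * overlap
    iu = np.triu_indices(len(b), k=1)
    return int(dist[iu].min())


def generate_constant_weight_code(
    n_bits: int,
    weight: int,
    min_distance: int,
    n_needed: int,
    seed: int = 0,
) -> Codebook:
    """Generate a constant-weight code with pairwise distance >= min_distance.

    Deterministic given ``seed``. Uses the position-sum-class construction
    (guaranteeing ``floor(C(n_bits, weight) / n_bits)`` words for distance 4)
    followed by greedy augmentation in a seeded shuffled order. Raises
    :class:`CodeInfeasibleError` (carrying the best count achieved) when the
    exhaustive greedy pass ends below ``n_needed``.
    """
    if not (n_bits >= weight >= 1):
        raise ValueError("require n_bits >= weight >= 1")
    if min_distance % 2 != 0 or min_distance < 2:
        raise ValueError("min_distance must be a positive even integer "
                         "(constant-weight codes have even pairwise distances)")
    if n_needed < 1:
        raise ValueError("n_needed must be >= 1")

    all_words = np.zeros(
        (0, n_bits), dtype=np.uint8
    )
    combos = list(itertools.combinations(range(n_bits), weight))
    all_words = np.zeros((len(combos), n_bits), dtype=np.uint8)
    for i, combo in enumerate(combos):
        all_words[i, list(combo)] = 1

    rng = np.random.default_rng(seed)

    if min_distance <= 2:
        # every pair of distinct constant-weight words is already >= 2 apart
        chosen = all_words
    else:
        pos_sums = all_words @ np.arange(n_bits)
        classes = pos_sums % n_bits
        counts = np.bincount(classes, minlength=n_bits)
        best_class = int(np.argmax(counts))
        seed_mask = classes == best_class
        chosen_list = list(np.flatnonzero(seed_mask))
        if min_distance > 4:
            # the class construction only guarantees distance 4; fall back to
            # pure greedy from scratch for stricter codes
            chosen_list = []
        rest = np.flatnonzero(~seed_mask) if chosen_list else np.arange(len(all_words))
        rest = rest[rng.permutation(len(rest))]

        max_overlap = weight - min_distance // 2
        chosen_bits = all_words[chosen_list].astype(np.int32)
        for idx in rest:
            cand = all_words[idx].astype(np.int32)
            if len(chosen_bits):
                if int((chosen_bits @ cand).max()) > max_overlap:
                    continue
            chosen_list.append(int(idx))
            chosen_bits = np.vstack([chosen_bits, cand[None, :]]) if len(chosen_bits) else cand[None, :]
        chosen = all_words[chosen_list]

    if len(chosen) < n_needed:
        raise CodeInfeasibleError(
            f"search exhausted at {len(chosen)} codewords "
            f"(< {n_needed} requested) for (n={n_bits}, w={weight}, d={min_distance})",
            best_count=len(chosen),
        )

    codewords = [
        Codeword(bits=tuple(int(b) for b in row), index=i)
        for i, row in enumerate(chosen)
    ]
    return Codebook(
        n_bits=n_bits,
        weight=weight,
        min_distance=min_distance,
        codewords=codewords,
        seed=seed,
    )


def assign_targets(
    codebook: Codebook,
    target_names: list,
    n_blanks: int,
    seed: int = 0,
) -> Codebook:
    """Randomly assign target names to codewords and flag blank codewords.

    A seeded permutation of codeword indices maps names onto a subset of
    codewords bijectively; the next ``n_blanks`` codewords are flagged blank;
    anything left over stays unused.
    """
    if len(set(target_names)) != len(target_names):
        raise ValueError("target names must be unique")
    if len(target_names) + n_blanks > len(codebook):
        raise ValueError(
            f"codebook has {len(codebook)} codewords; cannot assign "
            f"{len(target_names)} targets + {n_blanks} blanks"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(codebook))
    names = {int(order[i]): name for i, name in enumerate(target_names)}
    blanks = {int(i): False for i in range(len(codebook))}
    for j in range(len(target_names), len(target_names) + n_blanks):
        blanks[int(order[j])] = True
    return replace(codebook, target_names=names, blank_flags=blanks)


def schedule_rounds(codebook: Codebook, colors_per_round: int) -> Codebook:
    """Assign bits consecutively to (round, channel) imaging slots."""
    if colors_per_round < 1:
        raise ValueError("colors_per_round must be >= 1")
    schedule = {
        bit: (bit // colors_per_round, bit % colors_per_round)
        for bit in range(codebook.n_bits)
    }
    return replace(codebook, schedule=schedule)


def n_rounds(codebook: Codebook) -> int:
    if not codebook.schedule:
        raise ValueError("codebook has no schedule")
    return 1 + max(r for r, _ in codebook.schedule.values())


def decode_bit_vector(
    bits,
    codebook: Codebook,
    max_correction: int = 1,
) -> DecodeCall:
    """Decode one binary vector against the codebook.

    Exact matches decode at distance 0. Otherwise, if exactly one codeword
    lies within ``max_correction`` (0 or 1) the call is made with
    ``corrected_bit`` set; distance ties or everything farther away give
    ``no_call``. Blank codewords decode like coding words but the outcome is
    ``"blank"``.
    """
    if max_correction not in (0, 1):
        raise ValueError("max_correction must be 0 or 1")
    vec = np.asarray(bits, dtype=np.int32)
    if vec.shape != (codebook.n_bits,):
        raise ValueError(f"bit vector must have length {codebook.n_bits}")
    mat = codebook.bit_matrix.astype(np.int32)
    dist = np.abs(mat - vec[None, :]).sum(axis=1)
    dmin = int(dist.min())
    if dmin > max_correction:
        return DecodeCall("no_call", None, dmin)
    hits = np.flatnonzero(dist == dmin)
    if len(hits) != 1:
        return DecodeCall("no_call", None, dmin)
    idx = int(codebook.codewords[hits[0]].index)
    corrected = None
    if dmin == 1:
        corrected = int(np.flatnonzero(mat[hits[0]] != vec)[0])
    outcome = "blank" if codebook.is_blank(idx) else "target"
    return DecodeCall(outcome, idx, dmin, corrected, codebook.name_of(idx))


def verify_code(codebook: Codebook) -> CodeReport:
    """Exhaustive O(K^2 n) verification of weight and minimum distance."""
    if len(codebook) < 1:
        raise ValueError("codebook must contain at least one codeword")
    bits = codebook.bit_matrix
    weights = frozenset(int(w) for w in bits.sum(axis=1))
    if len(codebook) == 1:
        return CodeReport(size=1, weights=weights, min_distance=None)
    return CodeReport(
        size=len(codebook),
        weights=weights,
        min_distance=_pairwise_min_distance(bits),
    )
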
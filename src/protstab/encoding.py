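"""Fixed-length numeric encoding of substitution records.

A record is encoded from a window of ``w`` consecutive residues centred on
the substitution site (positions beyond the sequence ends are padded), one
or more property scales, the mutant residue, and the measurement pH.

Vector layout (feature-major):

    [scale_1 over window pos 1..w | scale_2 over window | ... |
     mutant-residue value per scale | pH / ph_divisor]

giving length ``w*f + f + 1`` for ``f`` selected scales.  The window always
encodes the wild-type sequence; the mutant identity enters only through the
mutant block (default) or, optionally, as a centred difference
``(scale(mut) - scale(wt) + 1) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset, MutationInstance, NEGATIVE, POSITIVE
from .scales import PAD_TOKEN, ScaleRegistry


class EncodingError(ValueError):
    """Raised for invalid encoding specifications or inputs."""


@dataclass(frozen=True)
class EncodingSpec:
    """How to turn a mutation record into a numeric vector.

    Parameters
    ----------
    window_size : int
        Odd number of residues ``w`` encoded around the substitution site.
    features : tuple of str
        Ordered scale codes used for encoding (no duplicates).
    include_mutant_block : bool
        Append a block with the mutant residue's scale values (default on;
        without it, substitutions at one site are indistinguishable).
    mutant_mode : str
        ``"block"``: the mutant residue's own values; ``"delta"``: centred
        differences against the wild-type residue.
    ph_divisor : float
        pH is divided by this to land in [0, 1] (default 14).
    unknown_policy : str
        Residue-lookup policy passed to the scale registry.
    """

    window_size: int = 11
    features: tuple[str, ...] = ()
    include_mutant_block: bool = True
    mutant_mode: str = "block"
    ph_divisor: float = 14.0
    unknown_policy: str = "strict"

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise EncodingError(
                f"window size must be odd and positive, got {self.window_size}"
            )
        if not self.features:
            raise EncodingError("feature list must be non-empty")
        if len(set(self.features)) != len(self.features):
            raise EncodingError(f"duplicate feature codes in {self.features}")
        if self.mutant_mode not in ("block", "delta"):
            raise EncodingError(f"unknown mutant_mode {self.mutant_mode!r}")
        if self.ph_divisor <= 0:
            raise EncodingError("ph_divisor must be positive")
        object.__setattr__(self, "features", tuple(self.features))

    @property
    def vector_length(self) -> int:
        f = len(self.features)
        n = self.window_size * f + 1
        if self.include_mutant_block:
            n += f
        return n

    def validate_against(self, registry: ScaleRegistry) -> None:
        unknown = [c for c in self.features if c not in registry]
        if unknown:
            raise EncodingError(f"unregistered feature codes {unknown}")


def extract_window(sequence: str, position: int, w: int) -> str:
    """The ``w``-residue subsequence centred on 1-based ``position``.

    Out-of-range flanks are filled with the padding token, so the returned
    string always has length ``w`` with the substitution-site residue at the
    middle index ``(w - 1) // 2`` (0-based).
    """
    if w < 1 or w % 2 == 0:
        raise EncodingError(f"window size must be odd and positive, got {w}")
    if not (1 <= position <= len(sequence)):
        raise EncodingError(f"position {position} outside 1..{len(sequence)}")
    half = (w - 1) // 2
    i = position - 1
    chars = []
    for j in range(i - half, i + half + 1):
        chars.append(sequence[j] if 0 <= j < len(sequence) else PAD_TOKEN)
    return "".join(chars)


def encode(
    instance: MutationInstance, spec: EncodingSpec, registry: ScaleRegistry
) -> np.ndarray:
    """Encode one record as a float vector of length ``spec.vector_length``.

    Pure function: identical inputs give bit-identical vectors.
    """
    spec.validate_against(registry)
    window = extract_window(instance.sequence, instance.position, spec.window_size)
    parts: list[float] = []
    for code in spec.features:
        for res in window:
            parts.append(registry.value_of(code, res, spec.unknown_policy))
    if spec.include_mutant_block:
        for code in spec.features:
            mut_v = registry.value_of(code, instance.mut_residue, spec.unknown_policy)
            if spec.mutant_mode == "delta":
                wt_v = registry.value_of(
                    code, instance.wt_residue, spec.unknown_policy
                )
                parts.append((mut_v - wt_v + 1.0) / 2.0)
            else:
                parts.append(mut_v)
    parts.append(instance.ph / spec.ph_divisor)
    return np.asarray(parts, dtype=float)


def encode_dataset(
    dataset: Dataset, spec: EncodingSpec, registry: ScaleRegistry
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every record; returns ``(X, y)`` with labels mapped to +/-1.

    Row order follows the dataset order.  Per-record failures are re-raised
    with the offending row index.
    """
    if len(dataset) == 0:
        raise EncodingError("cannot encode an empty dataset")
    rows = []
    y = np.empty(len(dataset), dtype=int)
    for i, inst in enumerate(dataset):
        try:
            rows.append(encode(inst, spec, registry))
        except Exception as exc:
            raise EncodingError(f"record {i} ({inst.protein_id}): {exc}") from exc
        if inst.label == POSITIVE:
            y[i] = 1
        elif inst.label == NEGATIVE:
            y[i] = -1
        else:
            raise EncodingError(f"record {i} ({inst.protein_id}): unlabelled")
    return np.vstack(rows), y


@dataclass
class FeatureBlocks:
    """Pre-computed per-scale encoding blocks for fast subset assembly.

    Used by the feature-subset search: encoding every candidate subset from
    scratch would redo the same residue lookups thousands of times.  The
    assembled matrix is identical to :func:`encode_dataset` with the same
    feature order (checked in tests).
    """

    window_size: int
    codes: tuple[str, ...]
    window: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    mutant: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    ph: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    y: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def assemble(self, features: tuple[str, ...] | list[str]) -> np.ndarray:
        cols = [self.window[c] for c in features]
        cols += [self.mutant[c][:, None] for c in features]
        cols.append(self.ph[:, None])
        return np.hstack(cols)


def precompute_blocks(
    dataset: Dataset,
    window_size: int,
    registry: ScaleRegistry,
    codes: tuple[str, ...] | None = None,
    unknown_policy: str = "strict",
    ph_divisor: float = 14.0,
) -> FeatureBlocks:
    codes = tuple(codes) if codes is not None else registry.codes
    n = len(dataset)
    windows = [
        extract_window(i.sequence, i.position, window_size) for i in dataset
    ]
    blocks = FeatureBlocks(window_size=window_size, codes=codes)
    for code in codes:
        win = np.empty((n, window_size))
        mut = np.empty(n)
        for i, inst in enumerate(dataset):
            for j, res in enumerate(windows[i]):
                win[i, j] = registry.value_of(code, res, unknown_policy)
            mut[i] = registry.value_of(code, inst.mut_residue, unknown_policy)
        blocks.window[code] = win
        blocks.mutant[code] = mut
    blocks.ph = np.array([i.ph / ph_divisor for i in dataset])
    blocks.y = np.array([1 if i.label == POSITIVE else -1 for i in dataset])
    return blocks


def write_svmlight(X: np.ndarray, y: np.ndarray, path) -> None:
    """Export an encoded matrix in the sparse ``label index:value`` format
    used by the classical SVM command-line tools (1-based indices)."""
    from sklearn.datasets import dump_svmlight_file

    dump_svmlight_file(X, y, str(path), zero_based=False)


def write_dense_tsv(X: np.ndarray, y: np.ndarray, path) -> None:
    import pandas as pd

    df = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(X.shape[1])])
    df.insert(0, "label", y)
    df.to_csv(path, sep="\t", index=False)
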
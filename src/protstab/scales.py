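"""Registry of per-residue amino-acid property scales.

Each scale assigns one real number to each of the 20 standard amino acids
(hydrophobicity, bulkiness, secondary-structure propensity, ...).  Scales are
bundled as plain-text files and grouped into four classes: biochemical,
structural, empirical and other biological features.  Before encoding, every
scale is min-max normalized to [0, 1] so that coordinates fed to a
distance-based kernel are commensurate (raw scales differ by orders of
magnitude, e.g. molecular weight ~75-204 Da versus propensity indices ~0-2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
#: Token used for window positions that fall outside the protein sequence.
PAD_TOKEN: str = "-"
#: Normalized value returned for the padding token: mid-scale, i.e. neutral.
PAD_VALUE: float = 0.5

CLASS_LABELS = ("biochemical", "structural", "empirical", "other")


class ScaleError(ValueError):
    """Raised for malformed scale files or invalid scale lookups."""


@dataclass(frozen=True)
class FeatureScale:
    """One named per-amino-acid property table.

    Parameters
    ----------
    code : str
        Short identifier (e.g. ``"Bu"`` for bulkiness).
    class_label : str
        One of :data:`CLASS_LABELS`.
    values : mapping
        Residue letter -> value.  Normalized to [0, 1] iff ``normalized``.
    raw_values : mapping
        The values as read from the source file (always unnormalized).
    source : str
        Citation or accession-style provenance string.
    description : str
        One-line description of the property.
    normalized : bool
        Whether ``values`` has been min-max mapped to [0, 1].
    """

    code: str
    class_label: str
    values: Mapping[str, float]
    raw_values: Mapping[str, float]
    source: str = ""
    description: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ScaleError(
                f"scale {self.code!r}: unknown class {self.class_label!r}"
            )
        missing = sorted(set(AMINO_ACIDS) - set(self.values))
        extra = sorted(set(self.values) - set(AMINO_ACIDS))
        if missing or extra:
            raise ScaleError(
                f"scale {self.code!r}: missing residues {missing}, "
                f"unexpected keys {extra}"
            )
        for aa, v in self.values.items():
            if not math.isfinite(v):
                raise ScaleError(f"scale {self.code!r}: non-finite value for {aa}")

    @property
    def mean(self) -> float:
        return sum(self.values.values()) / len(self.values)


def normalize(scale: FeatureScale) -> FeatureScale:
    """Affine-map a scale's values onto [0, 1].

    Idempotent: normalizing an already-normalized scale returns an equal
    scale.  A constant scale is degenerate (it carries no information and the
    affine map is undefined) and raises :class:`ScaleError`.
    """
    lo = min(scale.values.values())
    hi = max(scale.values.values())
    if hi == lo:
        raise ScaleError(f"scale {scale.code!r} is constant; cannot normalize")
    if scale.normalized:
        return scale
    span = hi - lo
    mapped = {aa: (v - lo) / span for aa, v in scale.values.items()}
    return replace(scale, values=mapped, normalized=True)


def _parse_scale_file(text: str, origin: str) -> FeatureScale:
    header: dict[str, str] = {}
    values: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ScaleError(f"{origin}:{lineno}: expected 'key: value'")
        key, _, raw = line.partition(":")
        key = key.strip()
        raw = raw.strip()
        if key in ("code", "class", "source", "description"):
            header[key] = raw
        elif len(key) == 1 and key in AMINO_ACIDS:
            try:
                values[key] = float(raw)
            except ValueError as exc:
                raise ScaleError(
                    f"{origin}: non-numeric value {raw!r} for residue {key}"
                ) from exc
        else:
            raise ScaleError(f"{origin}:{lineno}: unknown key {key!r}")
    for req in ("code", "class"):
        if req not in header:
            raise ScaleError(f"{origin}: missing header field {req!r}")
    missing = sorted(set(AMINO_ACIDS) - set(values))
    if missing:
        raise ScaleError(
            f"{origin}: scale {header['code']!r} lacks residues {missing}"
        )
    return FeatureScale(
        code=header["code"],
        class_label=header["class"],
        values=values,
        raw_values=dict(values),
        source=header.get("source", ""),
        description=header.get("description", ""),
        normalized=False,
    )


@dataclass
class ScaleRegistry:
    """Collection of normalized feature scales, keyed by code."""

    scales: dict[str, FeatureScale] = field(default_factory=dict)

    def add(self, scale: FeatureScale) -> None:
        if scale.code in self.scales:
            raise ScaleError(f"duplicate scale code {scale.code!r}")
        self.scales[scale.code] = normalize(scale)

    def __contains__(self, code: str) -> bool:
        return code in self.scales

    def __getitem__(self, code: str) -> FeatureScale:
        try:
            return self.scales[code]
        except KeyError:
            raise ScaleError(f"unknown scale code {code!r}") from None

    def __len__(self) -> int:
        return len(self.scales)

    def __iter__(self) -> Iterator[str]:
        return iter(self.scales)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.scales)

    def class_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in CLASS_LABELS}
        for s in self.scales.values():
            counts[s.class_label] += 1
        return counts

    def value_of(self, code: str, residue: str, policy: str = "strict") -> float:
        """Normalized value of ``residue`` on scale ``code``.

        The padding token maps to the neutral mid-scale value
        :data:`PAD_VALUE`.  Non-standard letters (B, Z, X, ...) raise under
        the default ``"strict"`` policy; ``policy="mean"`` substitutes the
        scale mean instead.
        """
        scale = self[code]
        if residue == PAD_TOKEN:
            return PAD_VALUE
        if residue in scale.values:
            return scale.values[residue]
        if policy == "mean":
            return scale.mean
        raise ScaleError(
            f"unknown residue {residue!r} for scale {code!r} (strict policy)"
        )

    def save(self, directory: str | Path) -> None:
        """Write one scale file per entry (raw values; normalization is
        recomputed on load, so the round-trip is bit-identical)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for code, scale in self.scales.items():
            lines = [
                f"code: {scale.code}",
                f"class: {scale.class_label}",
                f"source: {scale.source}",
                f"description: {scale.description}",
            ]
            for aa in AMINO_ACIDS:
                lines.append(f"{aa}: {scale.raw_values[aa]!r}")
            (directory / f"{code}.txt").write_text("\n".join(lines) + "\n")


def _bundled_scale_dir() -> Path:
    return Path(resources.files("protstab").joinpath("data", "scales"))  # type: ignore[arg-type]


def load_registry(scale_dir: str | Path | None = None) -> ScaleRegistry:
    """Load every scale file from ``scale_dir`` (default: bundled tables).

    Raises :class:`ScaleError` naming the offending file and key on any
    malformed table, and validates the expected class partition only for the
    bundled default set.
    """
    bundled = scale_dir is None
    directory = _bundled_scale_dir() if bundled else Path(scale_dir)
    files = sorted(directory.glob("*.txt"))
    if not files:
        raise ScaleError(f"no scale files found in {directory}")
    registry = ScaleRegistry()
    for path in files:
        registry.add(_parse_scale_file(path.read_text(), origin=str(path)))
    if bundled:
        expected = {"biochemical": 5, "structural": 5, "empirical": 3, "other": 7}
        counts = registry.class_counts()
        if counts != expected or len(registry) != 20:
            raise ScaleError(
                f"bundled registry corrupted: {len(registry)} scales, {counts}"
            )
    return registry
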
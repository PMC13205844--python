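"""Landmark schemas and annotated-image containers.

Two fixed landmark schemas are used throughout: 22 named soft-tissue
landmarks on frontal face images and 15 on profile images.  The ordering
of names is canonical: annotation files, model output vectors and error
tables all use the same order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

FRONTAL_VIEW = "frontal"
PROFILE_VIEW = "profile"

#: Canonical landmark orders.  Midline points run top-to-bottom
#: (Trichion .. Menton), followed by the paired lateral points.
FRONTAL_NAMES: tuple[str, ...] = (
    "Tr", "G", "N", "Prn", "Sn", "Phi", "Ls", "Stm", "Li", "Pg", "Gn", "Me",
    "GoL", "GoR", "ChR", "ChL", "AlL", "AlR", "ExL", "ExR", "EndR", "EndL",
)

PROFILE_NAMES: tuple[str, ...] = (
    "Tr", "G", "N", "Prn", "Col", "Al", "Sn", "Phi", "Ls", "Stm", "Li",
    "Pg", "Gn", "Me", "Go",
)

#: Midline landmarks share a single x coordinate in the frontal view.
FRONTAL_MIDLINE: tuple[str, ...] = (
    "Tr", "G", "N", "Prn", "Sn", "Phi", "Ls", "Stm", "Li", "Pg", "Gn", "Me",
)

#: Mirror-symmetric pairs in the frontal view (left name, right name).
FRONTAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("GoL", "GoR"), ("ChL", "ChR"), ("AlL", "AlR"),
    ("ExL", "ExR"), ("EndL", "EndR"),
)

#: Full anatomical names accepted as aliases for the abbreviations.
_FULL_NAME_ALIASES = {
    "Trichion": "Tr",
    "Glabella": "G",
    "Nasion": "N",
    "Pronasale": "Prn",
    "Columella": "Col",
    "Subnasale": "Sn",
    "Philtrum": "Phi",
    "Labium Superior": "Ls",
    "Stomion": "Stm",
    "Labium Inferior": "Li",
    "Pogonion": "Pg",
    "Gnathion": "Gn",
    "Menton": "Me",
    "Gonion": "Go",
    "Gonion Left": "GoL",
    "Gonion Right": "GoR",
    "Chelion": "Ch",
    "Chelion Left": "ChL",
    "Chelion Right": "ChR",
    "Alare": "Al",
    "Alare Left": "AlL",
    "Alare Right": "AlR",
    "Exocanthion": "Ex",
    "Exocanthion Left": "ExL",
    "Exocanthion Right": "ExR",
    "Endocanthion": "En",
    "Endocanthion Left": "EndL",
    "Endocanthion Right": "EndR",
}


class SchemaError(ValueError):
    """An annotation does not conform to its landmark schema."""


@dataclass(frozen=True)
class LandmarkSchema:
    """Ordered landmark-name list defining a view.

    Attributes
    ----------
    view : str
        Either ``"frontal"`` or ``"profile"``.
    names : tuple of str
        Ordered landmark abbreviations; 22 for frontal, 15 for profile.
    """

    view: str
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise SchemaError(f"duplicate landmark names in schema {self.view!r}")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_outputs(self) -> int:
        """Length of the flattened (x, y) coordinate vector."""
        return 2 * len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def resolve_name(self, label: str) -> str | None:
        """Map a file label (abbreviation or full name) to a schema name.

        Returns ``None`` for labels not in this schema.
        """
        label = label.strip()
        if label in self.names:
            return label
        canonical = _FULL_NAME_ALIASES.get(label)
        if canonical in self.names:
            return canonical
        return None


FRONTAL_SCHEMA = LandmarkSchema(FRONTAL_VIEW, FRONTAL_NAMES)
PROFILE_SCHEMA = LandmarkSchema(PROFILE_VIEW, PROFILE_NAMES)

_SCHEMAS = {FRONTAL_VIEW: FRONTAL_SCHEMA, PROFILE_VIEW: PROFILE_SCHEMA}


def get_schema(view: str) -> LandmarkSchema:
    """Return the canonical schema for a view name."""
    try:
        return _SCHEMAS[view]
    except KeyError:
        raise SchemaError(
            f"unknown view {view!r}; expected one of {sorted(_SCHEMAS)}"
        ) from None


@dataclass(frozen=True)
class PointAnnotation:
    """A single named landmark point.

    ``x`` is the column (rightward from the left edge), ``y`` the row
    (downward from the top edge), both in pixels, 0-based, pixel-centre.
    """

    name: str
    x: float
    y: float


@dataclass
class AnnotatedImage:
    """One face image plus its ordered named landmarks and metadata."""

    subject_id: str
    view: str
    pixels: np.ndarray  # H x W x 3, uint8
    width: int
    height: int
    landmarks: list[PointAnnotation]
    source_path: str = ""

    @property
    def schema(self) -> LandmarkSchema:
        return get_schema(self.view)

    def landmark_array(self) -> np.ndarray:
        """Landmarks as an (L, 2) float array of (x, y) rows in schema order."""
        return np.array([[p.x, p.y] for p in self.landmarks], dtype=float)


def points_from_array(coords: np.ndarray | Sequence[Sequence[float]],
                      schema: LandmarkSchema) -> list[PointAnnotation]:
    """Build schema-ordered PointAnnotations from an (L, 2) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(schema), 2):
        raise SchemaError(
            f"expected coordinates of shape ({len(schema)}, 2), got {coords.shape}"
        )
    return [PointAnnotation(n, float(x), float(y))
            for n, (x, y) in zip(schema.names, coords)]


def validate_annotation(img: AnnotatedImage) -> list[str]:
    """Quality-control check of one annotated image.

    Returns a list of human-readable violations; an empty list means the
    image passes.  Violations are data, not exceptions, so a cohort can be
    gated (images failing any check are excluded) without aborting.
    """
    violations: list[str] = []
    try:
        schema = get_schema(img.view)
    except SchemaError as exc:
        return [str(exc)]

    names = [p.name for p in img.landmarks]
    if names != list(schema.names):
        missing = [n for n in schema.names if n not in names]
        extra = [n for n in names if n not in schema.names]
        if missing:
            violations.append(f"missing landmarks: {', '.join(missing)}")
        if extra:
            violations.append(f"unexpected landmarks: {', '.join(extra)}")
        if not missing and not extra:
            violations.append("landmarks out of schema order")

    if img.pixels is not None:
        h, w = img.pixels.shape[:2]
        if (w, h) != (img.width, img.height):
            violations.append(
                f"pixel array is {w}x{h} but metadata says {img.width}x{img.height}"
            )

    for p in img.landmarks:
        if not (np.isfinite(p.x) and np.isfinite(p.y)):
            violations.append(f"{p.name}: non-finite coordinates ({p.x}, {p.y})")
        elif not (0 <= p.x < img.width and 0 <= p.y < img.height):
            violations.append(
                f"{p.name}: out of bounds ({p.x:.1f}, {p.y:.1f}) "
                f"for {img.width}x{img.height} image"
            )
    return violations


def quality_control(cohort: Iterable[AnnotatedImage]
                    ) -> tuple[list[AnnotatedImage], dict[str, list[str]]]:
    """Exclude subjects with incomplete, out-of-bounds or corrupt annotations.

    All images of a failing subject are dropped (subjects are the unit of
    inclusion).  Returns the surviving images and a map of excluded
    subject_id -> violations.
    """
    cohort = list(cohort)
    excluded: dict[str, list[str]] = {}
    for img in cohort:
        problems = validate_annotation(img)
        if problems:
            excluded.setdefault(img.subject_id, []).extend(
                f"{img.view}: {p}" for p in problems)
    kept = [img for img in cohort if img.subject_id not in excluded]
    return kept, excluded
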
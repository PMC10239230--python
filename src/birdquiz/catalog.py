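"""Species roster with expert-designated similar-song pairs.

The catalog is the static input of every other module: it fixes the set of
species a quiz can draw from and the similarity relation used for hard
distracters.  A small CSV dialect is the only on-disk representation:

    id,english_name,binomial,abbreviation,song_type,similar_abbrev,similarity_level

``similar_abbrev`` / ``similarity_level`` may be omitted entirely or left
empty; multiple similar species are semicolon-separated in both columns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

SONG_TYPES = ("song", "call")
#: "E" marks an easier discrimination, "D" a more difficult one.
SIMILARITY_LEVELS = ("E", "D")

REQUIRED_COLUMNS = ("id", "english_name", "binomial", "abbreviation", "song_type")
OPTIONAL_COLUMNS = ("similar_abbrev", "similarity_level")

#: A quiz needs at least five distinct choices.
MIN_CATALOG_SIZE = 5


class CatalogError(ValueError):
    """Raised when a catalog file or roster fails validation."""


@dataclass(frozen=True)
class SimilarRef:
    """Reference to a confusable species at a given similarity level."""

    abbreviation: str
    level: str

    def __post_init__(self) -> None:
        if self.level not in SIMILARITY_LEVELS:
            raise CatalogError(
                f"similarity level must be one of {SIMILARITY_LEVELS}, got {self.level!r}"
            )


@dataclass(frozen=True)
class Species:
    """One catalog entry.

    ``similar`` holds zero or more :class:`SimilarRef`; the bundled roster has
    at most one per species, but the model deliberately allows several.
    """

    id: int
    english_name: str
    binomial: str
    abbreviation: str
    song_type: str
    similar: tuple[SimilarRef, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.song_type not in SONG_TYPES:
            raise CatalogError(
                f"{self.abbreviation}: song_type must be one of {SONG_TYPES}, "
                f"got {self.song_type!r}"
            )


class SpeciesCatalog:
    """Ordered, validated species roster.

    Iterating yields :class:`Species` in id order; ``catalog[abbrev]`` looks a
    species up by its four-letter code.
    """

    def __init__(self, species: list[Species] | tuple[Species, ...]):
        self.species: tuple[Species, ...] = tuple(species)
        self._by_abbrev: dict[str, Species] = {}
        self._validate()

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self) -> Iterator[Species]:
        return iter(self.species)

    def __getitem__(self, abbreviation: str) -> Species:
        return self._by_abbrev[abbreviation]

    def __contains__(self, abbreviation: str) -> bool:
        return abbreviation in self._by_abbrev

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(s.abbreviation for s in self.species)

    def similar_of(self, abbreviation: str) -> tuple[SimilarRef, ...]:
        """Similar-species references of one species (possibly empty)."""
        return self._by_abbrev[abbreviation].similar

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        if len(self.species) < MIN_CATALOG_SIZE:
            raise CatalogError(
                f"catalog needs at least {MIN_CATALOG_SIZE} species, "
                f"got {len(self.species)}"
            )
        for row, sp in enumerate(self.species, start=1):
            if sp.abbreviation in self._by_abbrev:
                raise CatalogError(
                    f"row {row}: duplicate abbreviation {sp.abbreviation!r}"
                )
            self._by_abbrev[sp.abbreviation] = sp
        ids = [sp.id for sp in self.species]
        if ids != list(range(1, len(ids) + 1)):
            raise CatalogError("species ids must be contiguous from 1 in order")
        # Similarity must resolve and be symmetric with equal level.
        for sp in self.species:
            for ref in sp.similar:
                if ref.abbreviation not in self._by_abbrev:
                    raise CatalogError(
                        f"{sp.abbreviation}: dangling similar reference "
                        f"{ref.abbreviation!r}"
                    )
                if ref.abbreviation == sp.abbreviation:
                    raise CatalogError(f"{sp.abbreviation}: similar to itself")
                back = self._by_abbrev[ref.abbreviation].similar
                if not any(
                    b.abbreviation == sp.abbreviation and b.level == ref.level
                    for b in back
                ):
                    raise CatalogError(
                        f"similarity not symmetric: {sp.abbreviation} -> "
                        f"{ref.abbreviation} ({ref.level}) has no matching "
                        "back-reference"
                    )


# -- I/O --------------------------------------------------------------------


def _parse_similar(similar_field: str, level_field: str, abbrev: str) -> tuple[SimilarRef, ...]:
    similars = [s for s in similar_field.split(";") if s] if similar_field else []
    levels = [s for s in level_field.split(";") if s] if level_field else []
    if len(similars) != len(levels):
        raise CatalogError(
            f"{abbrev}: similar_abbrev and similarity_level counts differ"
        )
    return tuple(SimilarRef(a, lv) for a, lv in zip(similars, levels))


def load_catalog(path: str | Path) -> SpeciesCatalog:
    """Read and validate a catalog CSV.

    Raises :class:`CatalogError` on a malformed header, duplicate
    abbreviations, dangling or asymmetric similarity references, or a roster
    smaller than :data:`MIN_CATALOG_SIZE`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise CatalogError(f"{path}: missing columns {missing}")
        unknown = [c for c in header if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
        if unknown:
            raise CatalogError(f"{path}: unknown columns {unknown}")
        species = []
        for row in reader:
            try:
                sp = Species(
                    id=int(row["id"]),
                    english_name=row["english_name"],
                    binomial=row["binomial"],
                    abbreviation=row["abbreviation"],
                    song_type=row["song_type"].lower(),
                    similar=_parse_similar(
                        (row.get("similar_abbrev") or "").strip(),
                        (row.get("similarity_level") or "").strip(),
                        row["abbreviation"],
                    ),
                )
            except (KeyError, ValueError) as exc:
                if isinstance(exc, CatalogError):
                    raise
                raise CatalogError(f"{path}: bad row {row!r}: {exc}") from exc
            species.append(sp)
    return SpeciesCatalog(species)


def write_catalog(catalog: SpeciesCatalog, path: str | Path) -> None:
    """Write a catalog in the same CSV dialect ``load_catalog`` reads."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS + OPTIONAL_COLUMNS)
        for sp in catalog:
            writer.writerow(
                [
                    sp.id,
                    sp.english_name,
                    sp.binomial,
                    sp.abbreviation,
                    sp.song_type,
                    ";".join(r.abbreviation for r in sp.similar),
                    ";".join(r.level for r in sp.similar),
                ]
            )


def builtin_catalog() -> SpeciesCatalog:
    """The packaged 26-species roster used throughout the default protocol."""
    ref = resources.files("birdquiz.data").joinpath("species.csv")
    with resources.as_file(ref) as path:
        return load_catalog(path)
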
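"""TF-target gene-set libraries (GMT format) and library collections.

A :class:`TFLibrary` maps transcription-factor ids to target-gene sets over
an explicit background universe.  Several libraries — built from ChIP-seq,
co-expression, literature curation and so on — are grouped into a
:class:`LibraryCollection` so that enrichment evidence can be integrated
across annotation resources.

The background universe defaults to the measured platform (the expression
matrix's gene ids) rather than the library's own union: enrichment must be
assessed against what could have been detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)


class GMTParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class LibraryValidationError(ValueError):
    pass


@dataclass(frozen=True)
class TFLibrary:
    """One TF-target annotation resource."""

    name: str
    sets: dict  # tf_id -> frozenset of target gene ids
    universe: frozenset

    def __post_init__(self) -> None:
        for tf, targets in self.sets.items():
            if not targets:
                raise LibraryValidationError(
                    f"library {self.name!r}: TF {tf!r} has an empty target set"
                )
            stray = targets - self.universe
            if stray:
                raise LibraryValidationError(
                    f"library {self.name!r}: TF {tf!r} has targets outside "
                    f"the universe, e.g. {sorted(stray)[:3]}"
                )

    @property
    def tf_ids(self) -> list[str]:
        return sorted(self.sets)

    @property
    def n_tfs(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class LibraryCollection:
    """Ordered group of TF-target libraries sharing a gene universe."""

    libraries: tuple

    def __post_init__(self) -> None:
        names = [lib.name for lib in self.libraries]
        if len(set(names)) != len(names):
            raise LibraryValidationError(f"duplicate library names in {names}")

    def __len__(self) -> int:
        return len(self.libraries)

    def __iter__(self):
        return iter(self.libraries)

    def __getitem__(self, name: str) -> TFLibrary:
        for lib in self.libraries:
            if lib.name == name:
                return lib
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [lib.name for lib in self.libraries]

    @property
    def tf_union(self) -> frozenset:
        out: set = set()
        for lib in self.libraries:
            out |= set(lib.sets)
        return frozenset(out)


def read_gmt(
    path: str | Path,
    universe: set | frozenset | None = None,
    name: str | None = None,
    uppercase: bool = True,
) -> TFLibrary:
    """Parse one GMT file into a :class:`TFLibrary`.

    Genes outside ``universe`` are dropped (count logged); sets emptied by
    the filter are removed with a warning.  TF and gene ids are upper-cased
    once so matching downstream is case-insensitive but deterministic.
    """
    path = Path(path)
    name = name or path.stem
    sets: dict = {}
    dropped = 0
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GMTParseError(
                f"expected >=3 tab-separated fields, found {len(fields)}", i
            )
        tf = fields[0].upper() if uppercase else fields[0]
        if tf in sets:
            raise GMTParseError(f"duplicate set name {tf!r}", i)
        genes = {g.upper() if uppercase else g for g in fields[2:] if g}
        if universe is not None:
            kept = genes & set(universe)
            dropped += len(genes) - len(kept)
            genes = kept
        if not genes:
            logger.warning(
                "library %s: set %r empty after universe filter, removed",
                name,
                tf,
            )
            continue
        sets[tf] = frozenset(genes)
    if dropped:
        logger.info(
            "library %s: dropped %d target genes outside the universe",
            name,
            dropped,
        )
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return TFLibrary(name=name, sets=sets, universe=frozenset(universe))


def write_gmt(lib: TFLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tf in sorted(lib.sets):
            genes = "\t".join(sorted(lib.sets[tf]))
            fh.write(f"{tf}\t{lib.name}\t{genes}\n")


def load_collection(
    manifest: str | Path | dict,
    universe: set | frozenset | None = None,
) -> LibraryCollection:
    """Load libraries listed in a YAML manifest (name -> GMT path).

    Relative paths resolve against the manifest's directory.  A plain dict
    of ``name -> path`` is accepted directly.
    """
    base = Path(".")
    if not isinstance(manifest, dict):
        mpath = Path(manifest)
        base = mpath.parent
        with open(mpath) as fh:
            manifest = yaml.safe_load(fh)
        if not isinstance(manifest, dict) or not manifest:
            raise LibraryValidationError("manifest must map names to paths")
    libs = [
        read_gmt(base / p, universe=universe, name=n)
        for n, p in manifest.items()
    ]
    return LibraryCollection(libraries=tuple(libs))


def validate_collection(collection: LibraryCollection) -> dict:
    """Summary report: per-library TF counts, set sizes, universe coverage."""
    if len(collection) == 0:
        raise LibraryValidationError("empty library collection")
    per_library = {}
    for lib in collection:
        sizes = sorted(len(s) for s in lib.sets.values())
        per_library[lib.name] = {
            "n_tfs": lib.n_tfs,
            "set_size_min": sizes[0],
            "set_size_max": sizes[-1],
            "set_size_median": sizes[len(sizes) // 2],
            "universe_size": len(lib.universe),
        }
    union = collection.tf_union
    coverage = {
        tf: sum(1 for lib in collection if tf in lib.sets) for tf in union
    }
    return {
        "n_libraries": len(collection),
        "per_library": per_library,
        "n_tfs_union": len(union),
        "tf_coverage": coverage,
    }
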
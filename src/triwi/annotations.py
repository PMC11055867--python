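"""Gene-set annotation catalogs (GMT format with a level tag).

Each term carries an integer ontology level in its GMT description field
as ``level=<int>``; deep (specific) terms have high levels.  The level is
consumed as catalog metadata — the ontology graph itself is never
traversed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import InputError


@dataclass(frozen=True)
class Term:
    name: str
    level: int
    genes: frozenset[str]


@dataclass
class AnnotationCatalog:
    """Named gene sets with level metadata over a fixed gene universe."""

    terms: dict[str, Term]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for tid, term in self.terms.items():
            if term.level < 1:
                raise InputError(f"term {tid!r} has level {term.level} < 1")
            stray = term.genes - self.universe
            if stray:
                raise InputError(
                    f"term {tid!r} contains genes outside the universe: {sorted(stray)[:5]}"
                )

    def filtered(self, min_level: int) -> "AnnotationCatalog":
        kept = {tid: t for tid, t in self.terms.items() if t.level >= min_level}
        return AnnotationCatalog(terms=kept, universe=self.universe)

    def terms_containing(self, gene_a: str, gene_b: str) -> list[str]:
        return sorted(
            tid for tid, t in self.terms.items() if gene_a in t.genes and gene_b in t.genes
        )

    # ------------------------------------------------------------------ I/O

    def to_gmt(self, path) -> None:
        lines = []
        for tid in sorted(self.terms):
            t = self.terms[tid]
            desc = f"{t.name}|level={t.level}"
            lines.append("\t".join([tid, desc] + sorted(t.genes)))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gmt(cls, path, universe=None) -> "AnnotationCatalog":
        path = Path(path)
        if not path.exists():
            raise InputError(f"GMT file not found: {path}")
        terms: dict[str, Term] = {}
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs id, description, >=1 gene")
            tid, desc, genes = fields[0], fields[1], fields[2:]
            level = None
            for chunk in desc.split("|"):
                if chunk.startswith("level="):
                    try:
                        level = int(chunk[len("level="):])
                    except ValueError:
                        raise InputError(f"{path}:{lineno}: malformed level tag {chunk!r}")
            if level is None:
                raise InputError(f"{path}:{lineno}: description lacks a 'level=<int>' tag")
            name = desc.split("|")[0]
            terms[tid] = Term(name=name, level=level, genes=frozenset(genes))
        if universe is None:
            universe = frozenset().union(*(t.genes for t in terms.values())) if terms else frozenset()
        return cls(terms=terms, universe=frozenset(universe))
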
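"""Readers and writers for the formats the pipeline touches.

Protein sequences travel as FASTA, trees as Newick, everything tabular
(annotations, expression counts, the gene-to-species map) as
tab-separated text with a header row.  Run configuration is plain
``key=value`` text.  Trees are :class:`dendropy.Tree` objects throughout
the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO

log = logging.getLogger(__name__)

#: Focal species of the study: five dictyostelids and three unicellular
#: amoebozoans, in phylogenetic order.
SPECIES_CODES = ("DD", "DP", "DL", "PP", "DF", "PhyP", "AC", "EH")
DICTYOSTELIDS = ("DD", "DP", "DL", "PP", "DF")
UNICELLULAR_AMOEBOZOA = ("PhyP", "AC", "EH")
#: Group 4 (most derived dictyostelid group) and the two major branches.
GROUP4 = frozenset({"DD", "DP"})
BRANCH_II = frozenset({"DD", "DP", "DL"})
BRANCH_I = frozenset({"PP", "DF"})

KINGDOMS = ("amoebozoa", "opisthokonta", "other_eukaryote", "prokaryote")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}

ANNOTATION_KINDS = ("domain", "sigp", "tm", "go", "kingdom")


@dataclass
class ProteinRecord:
    """One protein with its sequence and functional annotations.

    ``architecture`` is the ordered list of functional-domain tokens,
    ``sigp``/``tm`` the signal-peptide / transmembrane predictions, and
    ``kingdom`` the kingdom of origin (all eight focal species are
    amoebozoa; outgroup homologs carry their own kingdom).
    """

    id: str
    species: str = ""
    sequence: str = ""
    architecture: list[str] = field(default_factory=list)
    sigp: bool = False
    tm: bool = False
    go_terms: set[str] = field(default_factory=set)
    kingdom: str = "amoebozoa"


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into records (sequence fields only).

    The id is the first whitespace-separated token of the header; file
    order is preserved.  An empty file yields an empty list.  Sequences
    are uppercased and must be drawn from the 20 amino acids plus X.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"illegal residue(s) {sorted(bad)} in record '{entry.id}'"
            )
        if not seq:
            raise ValueError(f"empty sequence in record '{entry.id}'")
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record id(s): {dup}")
    return records


def write_fasta(records, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_newick(text: str, rooted: bool | None = None) -> dendropy.Tree:
    """Parse a Newick string into a tree.

    Branch lengths and internal support labels are kept; a missing
    length stays ``None`` rather than becoming zero.  Malformed input
    raises ``ValueError`` carrying the parser's position information.
    """
    rooting = "default-unrooted"
    if rooted is True:
        rooting = "force-rooted"
    elif rooted is False:
        rooting = "force-unrooted"
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting=rooting,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"Newick parse error: {exc}") from exc
    return tree


def read_newick_file(path: str | Path, rooted: bool | None = None) -> dendropy.Tree:
    return read_newick(Path(path).read_text(), rooted=rooted)


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick, round-trip stable to 1e-9 in lengths."""
    return tree.as_string(
        schema="newick",
        real_value_format_specifier=".17g",
        suppress_rooting=False,
        preserve_spaces=True,
    ).strip() + "\n"


def read_annotations(path: str | Path, records) -> tuple[list[ProteinRecord], int]:
    """Fill architecture/sigp/tm/go/kingdom fields from an annotation TSV.

    Each line is ``protein_id<TAB>kind<TAB>value`` with kind in
    {domain, sigp, tm, go, kingdom}; unknown kinds are rejected, lines
    for unknown protein ids are skipped with a warning.  Returns the
    records and the skipped-line count.  Unannotated fields keep their
    defaults (empty architecture, flags false, no GO terms).
    """
    by_id = {r.id: r for r in records}
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            pid, kind, value = parts
            if kind not in ANNOTATION_KINDS:
                raise ValueError(f"{path}:{lineno}: unknown annotation kind '{kind}'")
            rec = by_id.get(pid)
            if rec is None:
                log.warning("%s:%d: annotation for unknown protein id '%s' skipped",
                            path, lineno, pid)
                skipped += 1
                continue
            if kind == "domain":
                rec.architecture.append(value)
            elif kind == "sigp":
                rec.sigp = _parse_bool(value, path, lineno)
            elif kind == "tm":
                rec.tm = _parse_bool(value, path, lineno)
            elif kind == "go":
                rec.go_terms.add(value)
            elif kind == "kingdom":
                if value not in KINGDOMS:
                    raise ValueError(f"{path}:{lineno}: unknown kingdom '{value}'")
                rec.kingdom = value
    return list(records), skipped


def _parse_bool(value: str, path, lineno: int) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes", "t"):
        return True
    if v in ("false", "0", "no", "f"):
        return False
    raise ValueError(f"{path}:{lineno}: cannot parse boolean '{value}'")


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read the two-column gene-id → species-code table."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if parts[0] in mapping and mapping[parts[0]] != parts[1]:
                raise ValueError(f"{path}:{lineno}: conflicting species for '{parts[0]}'")
            mapping[parts[0]] = parts[1]
    return mapping


def write_species_map(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(mapping):
            fh.write(f"{gid}\t{mapping[gid]}\n")


def read_config(path: str | Path) -> dict[str, str]:
    """Read a plain ``key=value`` configuration file (``#`` comments)."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            cfg[key.strip()] = value.strip()
    return cfg
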
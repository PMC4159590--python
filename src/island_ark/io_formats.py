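"""Readers and writers for the standard formats the pipeline touches.

Four on-disk formats are supported:

* multi-record FASTA (sequence alignments; population in a ``|pop`` header
  suffix),
* GenePop 4- and 6-digit diploid genotype files,
* a plain TSV genotype dialect (``individual<TAB>population<TAB>a/b ...``,
  ``?`` for missing),
* TPS landmark files (``LM=``, ``CURVES=``/``POINTS=``, ``ID=``/``IMAGE=``,
  ``SCALE=``).

Every reader returns one of the typed containers below and every container
has a matching writer, so each format round-trips exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: sentinel for a missing allele (both members of a pair are MISSING or neither)
MISSING = -1

_VALID_BASES = set("ACGT-N")
#: IUPAC ambiguity codes collapsed to N on read
_AMBIGUOUS = set("RYSWKMBDHVU")


class ParseError(ValueError):
    """A file could not be parsed as the requested format."""


class DataError(ValueError):
    """Parsed content violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SequenceAlignment:
    """Equal-length nucleotide sequences with population labels.

    ``seqs`` is an ``(n, L)`` array of single characters over
    ``{A,C,G,T,-,N}``.  Every id is unique and carries a population label
    (``"all"`` when none was given).
    """

    ids: list[str]
    pops: dict[str, str]
    seqs: np.ndarray

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype="U1")
        if self.seqs.ndim != 2:
            raise DataError("seqs must be a 2-D character matrix")
        if len(self.ids) != self.seqs.shape[0]:
            raise DataError("ids and seqs disagree on sample count")
        if len(set(self.ids)) != len(self.ids):
            raise DataError("duplicate sequence ids")
        for i in self.ids:
            self.pops.setdefault(i, "all")
        bad = set(np.unique(self.seqs)) - _VALID_BASES
        if bad:
            raise DataError(f"illegal characters in alignment: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def L(self) -> int:
        return self.seqs.shape[1]

    def subset(self, pop: str) -> "SequenceAlignment":
        """Alignment restricted to samples of one population."""
        keep = [i for i in self.ids if self.pops[i] == pop]
        if not keep:
            raise DataError(f"no samples in population {pop!r}")
        idx = [self.ids.index(i) for i in keep]
        return SequenceAlignment(keep, {i: pop for i in keep}, self.seqs[idx])


@dataclass
class GenotypeTable:
    """Diploid microsatellite genotypes: individuals x loci allele-size pairs.

    ``alleles`` has shape ``(n_individuals, n_loci, 2)`` of integer repeat
    scores, pairs stored sorted; a missing genotype is ``(MISSING, MISSING)``
    — never half-missing.
    """

    individuals: list[str]
    pops: dict[str, str]
    loci: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, m = len(self.individuals), len(self.loci)
        if self.alleles.shape != (n, m, 2):
            raise DataError(
                f"alleles shape {self.alleles.shape} != ({n}, {m}, 2)")
        if len(set(self.individuals)) != n:
            raise DataError("duplicate individual labels")
        if m < 1 or n < 1:
            raise DataError("need at least one locus and one individual")
        missing = self.alleles == MISSING
        if np.any(missing[..., 0] != missing[..., 1]):
            raise DataError("half-missing genotype (MISSING is all-or-nothing)")
        ok = missing[..., 0] | (self.alleles > 0).all(axis=-1)
        if not ok.all():
            raise DataError("allele sizes must be positive integers")
        self.alleles = np.sort(self.alleles, axis=-1)
        for i in self.individuals:
            if i not in self.pops:
                raise DataError(f"individual {i!r} has no population label")

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for i in self.individuals:
            seen.setdefault(self.pops[i], None)
        return list(seen)

    def pop_mask(self, pop: str) -> np.ndarray:
        m = np.array([self.pops[i] == pop for i in self.individuals])
        if not m.any():
            raise DataError(f"no individuals in population {pop!r}")
        return m

    def subset(self, pops: list[str]) -> "GenotypeTable":
        keep = [i for i in self.individuals if self.pops[i] in pops]
        idx = [self.individuals.index(i) for i in keep]
        return GenotypeTable(keep, {i: self.pops[i] for i in keep},
                             list(self.loci), self.alleles[idx])


@dataclass
class LandmarkDataset:
    """Per-specimen 2-D landmark configurations.

    All specimens share the same landmark count ``k`` and the same
    fixed/semi-landmark designation; ``curve_order`` lists the semi-landmark
    indices in their along-curve order.
    """

    specimens: list[str]
    coords: np.ndarray            # (n, k, 2)
    semi_flags: np.ndarray        # (k,) bool
    curve_order: list[int] = field(default_factory=list)
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.semi_flags = np.asarray(self.semi_flags, dtype=bool)
        n = len(self.specimens)
        if self.coords.ndim != 3 or self.coords.shape[0] != n \
                or self.coords.shape[2] != 2:
            raise DataError("coords must have shape (n_specimens, k, 2)")
        k = self.coords.shape[1]
        if self.semi_flags.shape != (k,):
            raise DataError("semi_flags length != k")
        semis = set(np.flatnonzero(self.semi_flags).tolist())
        if sorted(self.curve_order) != sorted(semis):
            raise DataError("curve_order is not a permutation of the "
                            "semi-landmark indices")
        for s, cfg in zip(self.specimens, self.coords):
            d = np.linalg.norm(cfg[:, None] - cfg[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if (d == 0).any():
                raise DataError(f"specimen {s!r} has coincident landmarks")

    @property
    def n(self) -> int:
        return len(self.specimens)

    @property
    def k(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> SequenceAlignment:
    """Read an aligned FASTA file.

    Population labels are taken from a ``|pop`` suffix on the header
    (``>id|population``); sequences lacking one go to population ``"all"``.
    Lowercase is upcased and IUPAC ambiguity codes are collapsed to ``N``
    with a warning; any other character is a :class:`ParseError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no records")
    ids, pops, rows = [], {}, []
    L = None
    for rec in records:
        name = rec.id
        pop = "all"
        if "|" in name:
            name, pop = name.split("|", 1)
        seq = str(rec.seq).upper()
        if L is None:
            L = len(seq)
        elif len(seq) != L:
            raise DataError(
                f"{path}: record {name!r} has length {len(seq)}, expected {L}")
        chars = np.array(list(seq), dtype="U1")
        amb = np.isin(chars, sorted(_AMBIGUOUS))
        if amb.any():
            log.warning("%s: %d ambiguous base(s) in %s mapped to N",
                        path, int(amb.sum()), name)
            chars[amb] = "N"
        bad = ~np.isin(chars, sorted(_VALID_BASES))
        if bad.any():
            pos = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: illegal character {chars[pos]!r} in record "
                f"{name!r} at position {pos + 1}")
        ids.append(name)
        pops[name] = pop
        rows.append(chars)
    return SequenceAlignment(ids, pops, np.array(rows))


def write_fasta(aln: SequenceAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=f"{i}|{aln.pops[i]}", description="")
        for i, row in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# genotypes: GenePop and TSV
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, dialect: str = "genepop") -> GenotypeTable:
    """Read a diploid genotype table (``dialect`` in {"genepop", "tsv"})."""
    if dialect == "genepop":
        return _read_genepop(path)
    if dialect == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_genotypes(table: GenotypeTable, path: str | Path,
                    dialect: str = "genepop") -> None:
    if dialect == "genepop":
        _write_genepop(table, path)
    elif dialect == "tsv":
        _write_genotypes_tsv(table, path)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


def _split_allele_string(tok: str, ind: str) -> tuple[int, int]:
    if len(tok) % 2 != 0 or len(tok) not in (4, 6):
        raise ParseError(
            f"odd or unsupported allele string {tok!r} for {ind!r} "
            "(expected 4 or 6 digits)")
    w = len(tok) // 2
    a, b = int(tok[:w]), int(tok[w:])
    if (a == 0) != (b == 0):
        raise ParseError(f"half-missing genotype {tok!r} for {ind!r}")
    if a == 0:
        return MISSING, MISSING
    return a, b


def _read_genepop(path: str | Path) -> GenotypeTable:
    lines = [ln.rstrip() for ln in Path(path).read_text().splitlines()]
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GenePop file")
    body = lines[1:]
    # locus names: one per line, or a single comma-separated line
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        part = body[i].strip()
        if part:
            loci.extend(x.strip() for x in part.split(",") if x.strip())
        i += 1
    if not loci or i == len(body):
        raise ParseError(f"{path}: no loci or no Pop separator")
    individuals: list[str] = []
    pops: dict[str, str] = {}
    rows: list[list[int]] = []
    pop_idx = 0
    pop_label = None
    for ln in body[i:]:
        s = ln.strip()
        if not s:
            continue
        if s.lower() == "pop":
            pop_idx += 1
            pop_label = f"pop{pop_idx}"
            continue
        if "," not in s:
            raise ParseError(f"{path}: expected 'name , genotypes' line: {s!r}")
        name, geno = s.split(",", 1)
        name = name.strip()
        # writer convention: "population:individual" keeps labels round-trippable
        if ":" in name:
            pop_label, name = name.split(":", 1)
        if name in pops:
            raise ParseError(f"{path}: duplicate individual label {name!r}")
        toks = geno.split()
        if len(toks) != len(loci):
            raise ParseError(
                f"{path}: {name!r} has {len(toks)} genotypes for "
                f"{len(loci)} loci")
        pair_row: list[int] = []
        for tok in toks:
            a, b = _split_allele_string(tok, name)
            pair_row.extend((a, b))
        individuals.append(name)
        pops[name] = pop_label or "pop1"
        rows.append(pair_row)
    if not individuals:
        raise ParseError(f"{path}: no individuals")
    alleles = np.array(rows, dtype=np.int64).reshape(len(individuals),
                                                    len(loci), 2)
    return GenotypeTable(individuals, pops, loci, alleles)


def _write_genepop(table: GenotypeTable, path: str | Path) -> None:
    width = 3 if table.alleles.max(initial=0) > 99 else 2
    out = ["island-ark genotype export"]
    out.extend(table.loci)
    last_pop = None
    for i, ind in enumerate(table.individuals):
        pop = table.pops[ind]
        if pop != last_pop:
            out.append("Pop")
            last_pop = pop
        toks = []
        for a, b in table.alleles[i]:
            if a == MISSING:
                toks.append("0" * (2 * width))
            else:
                toks.append(f"{a:0{width}d}{b:0{width}d}")
        out.append(f"{pop}:{ind} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


def _read_genotypes_tsv(path: str | Path) -> GenotypeTable:
    lines = [ln.rstrip("\r\n") for ln in Path(path).read_text().splitlines()
             if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    sep = "\t" if "\t" in lines[0] else ","
    header = [c.strip() for c in lines[0].split(sep)]
    if len(header) < 3 or header[0] != "individual" or header[1] != "population":
        raise ParseError(
            f"{path}: header must start 'individual{sep}population{sep}<loci>'")
    loci = header[2:]
    individuals, pops, rows = [], {}, []
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(sep)]
        if len(cells) != len(header):
            raise ParseError(f"{path}: row width mismatch: {ln!r}")
        name, pop = cells[0], cells[1]
        if name in pops:
            raise ParseError(f"{path}: duplicate individual label {name!r}")
        pair_row: list[int] = []
        for cell, locus in zip(cells[2:], loci):
            if cell == "?":
                pair_row.extend((MISSING, MISSING))
                continue
            m = re.fullmatch(r"(\d+)/(\d+)", cell)
            if not m:
                raise ParseError(
                    f"{path}: bad genotype {cell!r} at {name!r}/{locus}")
            pair_row.extend((int(m.group(1)), int(m.group(2))))
        individuals.append(name)
        pops[name] = pop
        rows.append(pair_row)
    alleles = np.array(rows, dtype=np.int64).reshape(len(individuals),
                                                    len(loci), 2)
    return GenotypeTable(individuals, pops, loci, alleles)


def _write_genotypes_tsv(table: GenotypeTable, path: str | Path) -> None:
    out = ["\t".join(["individual", "population"] + list(table.loci))]
    for i, ind in enumerate(table.individuals):
        cells = [ind, table.pops[ind]]
        for a, b in table.alleles[i]:
            cells.append("?" if a == MISSING else f"{a}/{b}")
        out.append("\t".join(cells))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# TPS landmark files
# ---------------------------------------------------------------------------

_TPS_KEY = re.compile(r"^(LM|CURVES|POINTS|ID|IMAGE|SCALE)\s*=\s*(.*)$",
                      re.IGNORECASE)


def read_tps(path: str | Path) -> LandmarkDataset:
    """Read a TPS landmark file.

    Fixed landmarks (the ``LM=`` block) come first; points from ``CURVES``
    blocks are appended in file order and flagged as semi-landmarks.
    ``SCALE=`` multiplies all coordinates of its specimen.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    specimens: list[str] = []
    all_coords: list[np.ndarray] = []
    flags_ref: np.ndarray | None = None
    order_ref: list[int] | None = None

    i, spec_no = 0, 0
    while i < len(lines):
        if not lines[i]:
            i += 1
            continue
        m = _TPS_KEY.match(lines[i])
        if not m or m.group(1).upper() != "LM":
            raise ParseError(f"{path}: expected LM= at line {i + 1}")
        n_fixed = int(m.group(2))
        i += 1
        spec_no += 1

        def read_points(count: int, what: str) -> list[list[float]]:
            nonlocal i
            pts = []
            while len(pts) < count and i < len(lines):
                if not lines[i]:
                    i += 1
                    continue
                if _TPS_KEY.match(lines[i]):
                    break
                xy = lines[i].split()
                if len(xy) != 2:
                    raise ParseError(
                        f"{path}: bad coordinate line {i + 1}: {lines[i]!r}")
                pts.append([float(xy[0]), float(xy[1])])
                i += 1
            if len(pts) != count:
                raise ParseError(
                    f"{path}: {what} expected {count} points, got {len(pts)} "
                    f"(specimen {spec_no})")
            return pts

        fixed = read_points(n_fixed, "LM block")
        curves: list[list[list[float]]] = []
        label = f"specimen{spec_no}"
        scale = None
        while i < len(lines):
            if not lines[i]:
                i += 1
                continue
            m = _TPS_KEY.match(lines[i])
            if not m:
                raise ParseError(f"{path}: unexpected line {i + 1}: {lines[i]!r}")
            key, val = m.group(1).upper(), m.group(2).strip()
            if key == "LM":
                break
            i += 1
            if key == "CURVES":
                for _ in range(int(val)):
                    pm = _TPS_KEY.match(lines[i]) if i < len(lines) else None
                    if not pm or pm.group(1).upper() != "POINTS":
                        raise ParseError(
                            f"{path}: CURVES block without POINTS= "
                            f"(specimen {spec_no})")
                    npts = int(pm.group(2))
                    i += 1
                    curves.append(read_points(npts, "curve"))
            elif key in ("ID", "IMAGE"):
                label = val or label
            elif key == "SCALE":
                scale = float(val)
        coords = np.array(fixed + [p for c in curves for p in c], dtype=float)
        if scale is not None:
            coords = coords * scale
        flags = np.zeros(len(coords), dtype=bool)
        flags[n_fixed:] = True
        if flags_ref is None:
            flags_ref, order_ref = flags, list(range(n_fixed, len(coords)))
        elif len(coords) != len(flags_ref) or (flags != flags_ref).any():
            raise DataError(
                f"{path}: specimen {label!r} has k={len(coords)}, "
                f"expected {len(flags_ref)} with matching semi-landmarks")
        specimens.append(label)
        all_coords.append(coords)

    if not specimens:
        raise ParseError(f"{path}: no records")
    return LandmarkDataset(specimens, np.array(all_coords), flags_ref,
                           order_ref or [])


def write_tps(ds: LandmarkDataset, path: str | Path) -> None:
    n_fixed = int((~ds.semi_flags).sum())
    n_semi = ds.k - n_fixed
    out: list[str] = []
    fixed_idx = np.flatnonzero(~ds.semi_flags)
    for s, cfg in zip(ds.specimens, ds.coords):
        out.append(f"LM={n_fixed}")
        for j in fixed_idx:
            out.append(f"{cfg[j, 0]:.10g} {cfg[j, 1]:.10g}")
        if n_semi:
            out.append("CURVES=1")
            out.append(f"POINTS={n_semi}")
            for j in ds.curve_order:
                out.append(f"{cfg[j, 0]:.10g} {cfg[j, 1]:.10g}")
        out.append(f"ID={s}")
    Path(path).write_text("\n".join(out) + "\n")
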
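"""Readers and writers for the package's plain-text formats.

FASTA (Bio.SeqIO) for sequences and family alignments, Newick (dendropy) for
phylogenies, and two TSV dialects:

* pocket-profile matrix sets — ``#allele <id>`` header, nine data lines
  ``pos<TAB>`` followed by 20 one-decimal weights in A..Y alphabetical
  residue order, and optional ``#threshold <percent> <value>`` lines (the
  route for loading a published matrix/threshold set);
* per-substitution ΔΔG° tables —
  ``position<TAB>wt_aa<TAB>mut_aa<TAB>ddG_kcal_per_mol`` with a required
  wild-type self row per position.

Parse failures always name the file, line number and offending field.
"""

from __future__ import annotations

from pathlib import Path
from typing import TextIO

import dendropy
from Bio import SeqIO

from .alphabet import AMINO_ACIDS, validate_sequence
from .epitope import AllelePanel, PocketProfileMatrix


class InputError(Exception):
    """A user input failed to parse or validate (CLI exit code 2)."""


def _fail(path, lineno: int, msg: str):
    raise InputError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta_single(path) -> tuple[str, str]:
    """Read exactly one record; multi-record targets are an error, not a pick."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise InputError(
            f"{path}: expected a single-record FASTA for the target, found "
            f"{len(records)} records"
        )
    rec = records[0]
    try:
        seq = validate_sequence(str(rec.seq), what=f"record {rec.id!r}")
    except ValueError as e:
        raise InputError(f"{path}: {e}") from None
    return rec.id, seq


def read_alignment_fasta(path) -> dict[str, str]:
    """Read an aligned FASTA into an ordered id -> gapped-row mapping."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise InputError(f"{path}: duplicate alignment id {rec.id!r}")
        rows[rec.id] = str(rec.seq).upper()
    if not rows:
        raise InputError(f"{path}: no FASTA records found")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise InputError(f"{path}: alignment rows have unequal lengths {sorted(lengths)}")
    return rows


def read_newick(path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as e:  # dendropy raises several parse error types
        raise InputError(f"{path}: failed to parse Newick tree: {e}") from None


# ---------------------------------------------------------------------------
# Pocket-profile matrix dialect
# ---------------------------------------------------------------------------


def load_matrix_file(path, window: int = 9) -> list[PocketProfileMatrix]:
    """Load one or more pocket-profile matrices from the TSV dialect."""
    path = Path(path)
    matrices: list[PocketProfileMatrix] = []
    cur_id: str | None = None
    cur_rows: dict[int, list[float]] = {}
    cur_thresholds: dict[int, float] = {}
    start_line = 0

    def flush(lineno: int) -> None:
        nonlocal cur_id, cur_rows, cur_thresholds
        if cur_id is None:
            return
        missing = sorted(set(range(1, window + 1)) - set(cur_rows))
        if missing:
            _fail(path, lineno, f"matrix {cur_id!r}: missing data lines for positions {missing}")
        weights = [cur_rows[p] for p in range(1, window + 1)]
        matrices.append(
            PocketProfileMatrix(cur_id, weights, thresholds=cur_thresholds, window=window)
        )
        cur_id, cur_rows, cur_thresholds = None, {}, {}

    with open(path) as fh:
        lineno = 0
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#allele"):
                flush(lineno)
                parts = line.split(maxsplit=1)
                if len(parts) != 2 or not parts[1].strip():
                    _fail(path, lineno, "expected '#allele <id>'")
                cur_id = parts[1].strip()
                start_line = lineno
            elif line.startswith("#threshold"):
                if cur_id is None:
                    _fail(path, lineno, "'#threshold' before any '#allele' header")
                parts = line.split()
                if len(parts) != 3:
                    _fail(path, lineno, "expected '#threshold <percent> <value>'")
                try:
                    pct = int(parts[1])
                    val = float(parts[2])
                except ValueError:
                    _fail(path, lineno, f"non-numeric threshold fields {parts[1:]!r}")
                if not 1 <= pct <= 10:
                    _fail(path, lineno, f"threshold percent {pct} outside 1..10")
                cur_thresholds[pct] = val
            elif line.startswith("#"):
                continue  # comment
            else:
                if cur_id is None:
                    _fail(path, lineno, "data line before any '#allele' header")
                fields = line.split("\t")
                if len(fields) != 1 + len(AMINO_ACIDS):
                    _fail(
                        path,
                        lineno,
                        f"expected position + {len(AMINO_ACIDS)} weight columns, "
                        f"got {len(fields)} fields",
                    )
                try:
                    pos = int(fields[0])
                except ValueError:
                    _fail(path, lineno, f"non-integer position field {fields[0]!r}")
                if not 1 <= pos <= window:
                    _fail(path, lineno, f"position {pos} outside 1..{window}")
                if pos in cur_rows:
                    _fail(path, lineno, f"duplicate data line for position {pos}")
                try:
                    cur_rows[pos] = [float(x) for x in fields[1:]]
                except ValueError as e:
                    _fail(path, lineno, f"non-numeric weight: {e}")
        flush(lineno + 1)
    if not matrices:
        raise InputError(f"{path}: no matrices found")
    return matrices


def write_matrix_file(matrices: list[PocketProfileMatrix], fh: TextIO) -> None:
    for m in matrices:
        fh.write(f"#allele {m.allele_id}\n")
        for pct, val in sorted(m.thresholds.items()):
            fh.write(f"#threshold {pct} {val:g}\n")
        W = m.weights
        for p in range(m.window):
            fh.write(
                str(p + 1) + "\t" + "\t".join(f"{x:.1f}" for x in W[p]) + "\n"
            )


def load_panel(path, percent: int = 10) -> AllelePanel:
    return AllelePanel(load_matrix_file(path), percent_level=percent)


# ---------------------------------------------------------------------------
# ΔΔG° table dialect
# ---------------------------------------------------------------------------


def load_ddg_table(path) -> tuple[dict[tuple[int, str], float], dict[int, str]]:
    """Parse a ΔΔG° TSV; returns ((position, mutant) -> kcal/mol, position -> wt)."""
    path = Path(path)
    table: dict[tuple[int, str], float] = {}
    wt_of: dict[int, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("position", "pos"):
                continue
            if len(fields) != 4:
                _fail(path, lineno, f"expected 4 tab-separated fields, got {len(fields)}")
            try:
                pos = int(fields[0])
            except ValueError:
                _fail(path, lineno, f"non-integer position {fields[0]!r}")
            wt, mut = fields[1].strip().upper(), fields[2].strip().upper()
            for aa, name in ((wt, "wt_aa"), (mut, "mut_aa")):
                if len(aa) != 1 or aa not in AMINO_ACIDS:
                    _fail(path, lineno, f"invalid {name} {aa!r}")
            try:
                val = float(fields[3])
            except ValueError:
                _fail(path, lineno, f"non-numeric ddG {fields[3]!r}")
            if pos in wt_of and wt_of[pos] != wt:
                _fail(path, lineno, f"conflicting wild-type residue at position {pos}")
            wt_of[pos] = wt
            if (pos, mut) in table:
                _fail(path, lineno, f"duplicate row for position {pos}, mutant {mut}")
            table[(pos, mut)] = val
    if not table:
        raise InputError(f"{path}: no ddG rows found")
    return table, wt_of


def write_ddg_table(
    table: dict[tuple[int, str], float], wt_of: dict[int, str], fh: TextIO
) -> None:
    fh.write("position\twt_aa\tmut_aa\tddG_kcal_per_mol\n")
    for (pos, mut), val in sorted(table.items()):
        fh.write(f"{pos}\t{wt_of[pos]}\t{mut}\t{val:.4f}\n")
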
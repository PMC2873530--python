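"""Variant evaluation and display: metric columns, dot-strings, mutation lists.

Each designed variant is reported with its predicted epitope counts (E, by
default at both the 10% and 5% stringency levels) and the per-substitution
stability sums:

* B  — number of substitutions the relative-BLOSUM rule would disallow,
* C  — summed -ln weighted family frequency of the substitutions,
* ΔΔG° — summed relative predicted folding free-energy change, kcal/mol,
* S  — an optional externally computed epitope count (e.g. an affinity-based
  predictor run by the user); never computed here, rendered "n/a" if absent.

Sequence display follows the dot-string convention ('.' = wild type,
letter = substitution, e.g. "........T.F......") and the offset-aware
mutation-list convention ("V79T,L81F" when the first residue is numbered 71).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

from .alphabet import AMINO_ACIDS
from .design import Variant
from .epitope import AllelePanel, EpitopeProfile, scan_sequence
from .mutability import PenaltyTables


# ---------------------------------------------------------------------------
# Notation
# ---------------------------------------------------------------------------


def dot_string(variant: Variant, wildtype: str) -> str:
    """Render a variant against its wild type: '.' where identical."""
    if len(variant.sequence) != len(wildtype):
        raise ValueError("variant and wild type differ in length")
    return "".join(
        "." if a == b else a for a, b in zip(variant.sequence, wildtype)
    )


def parse_dot_string(text: str, wildtype: str, offset: int = 1) -> Variant:
    """Parse a dot-string back into a Variant (inverse of :func:`dot_string`)."""
    if len(text) != len(wildtype):
        raise ValueError(
            f"dot-string length {len(text)} does not match wild type ({len(wildtype)})"
        )
    chars: list[str] = []
    subs: list[tuple[int, str, str]] = []
    for i, (ch, wt) in enumerate(zip(text, wildtype), start=1):
        if ch == ".":
            chars.append(wt)
        elif ch.upper() in AMINO_ACIDS:
            ch = ch.upper()
            chars.append(ch)
            if ch != wt:
                subs.append((i, wt, ch))
        else:
            raise ValueError(f"invalid dot-string character {ch!r} at position {i}")
    return Variant(sequence="".join(chars), substitutions=subs)


def mutation_list(variant: Variant, offset: int = 1) -> str:
    """Offset-aware mutation names, e.g. "V79T,L81F" (first residue = offset)."""
    return ",".join(
        f"{wt}{pos + offset - 1}{mut}" for pos, wt, mut in variant.substitutions
    )


def parse_mutation_list(text: str, wildtype: str, offset: int = 1) -> Variant:
    """Parse "V79T,S84E"-style mutation lists against a wild type + offset."""
    chars = list(wildtype)
    subs: list[tuple[int, str, str]] = []
    text = text.strip()
    if text:
        for item in text.split(","):
            item = item.strip()
            if len(item) < 3 or item[0] not in AMINO_ACIDS or item[-1] not in AMINO_ACIDS:
                raise ValueError(f"malformed mutation {item!r}")
            try:
                num = int(item[1:-1])
            except ValueError:
                raise ValueError(f"malformed mutation {item!r}") from None
            pos = num - offset + 1
            if not 1 <= pos <= len(wildtype):
                raise ValueError(f"mutation {item!r} outside the sequence (offset {offset})")
            if wildtype[pos - 1] != item[0]:
                raise ValueError(
                    f"mutation {item!r}: wild type at {num} is {wildtype[pos - 1]}, not {item[0]}"
                )
            mut = item[-1]
            chars[pos - 1] = mut
            if mut != item[0]:
                subs.append((pos, item[0], mut))
    subs.sort()
    return Variant(sequence="".join(chars), substitutions=subs)


# ---------------------------------------------------------------------------
# Metric columns
# ---------------------------------------------------------------------------


@dataclass
class VariantReport:
    """One row of the results table (wild type included as the zero row)."""

    label: str
    variant: Variant
    dot: str
    mutations: str
    E: dict[int, int]  # percent level -> total epitope count
    B: int | None = None
    C: float | None = None
    ddg_total: float | None = None
    S: int | None = None  # externally supplied, never computed internally
    percent_optimized: int | None = None

    def row(self, percents: Sequence[int] = (10, 5)) -> dict[str, object]:
        def fmt(x, nd=2):
            return "n/a" if x is None else (f"{x:.{nd}f}" if isinstance(x, float) else x)

        out: dict[str, object] = {
            "variant": self.label,
            "dot_string": self.dot,
            "mutations": self.mutations or "-",
        }
        for p in percents:
            out[f"E{p}"] = self.E.get(p, "n/a")
        out["B"] = fmt(self.B)
        out["C"] = fmt(self.C)
        out["ddG"] = fmt(self.ddg_total)
        out["S"] = "n/a" if self.S is None else self.S
        return out


def evaluate_variant(
    variant: Variant,
    panel: AllelePanel,
    penalties: PenaltyTables,
    percents: Sequence[int] = (10, 5),
    label: str = "",
    offset: int = 1,
    wildtype: str | None = None,
    S: int | None = None,
) -> VariantReport:
    """Compute the E/B/C/ΔΔG° columns for one variant.

    E re-scans the rendered sequence at each requested stringency level; the
    stability columns are sums over the substituted positions only, so the
    wild-type row is exactly (0, 0.00, 0.00).
    """
    wt = wildtype if wildtype is not None else variant.sequence
    E = {p: scan_sequence(panel, variant.sequence, p).total for p in percents}

    def total(table: Mapping[tuple[int, str], float] | None, kind: str):
        if table is None:
            return None
        vals = []
        for pos, _, mut in variant.substitutions:
            if (pos, mut) not in table:
                raise ValueError(
                    f"substitution at position {pos} ({mut}) outside {kind} table coverage"
                )
            vals.append(table[(pos, mut)])
        return sum(vals) if vals else (0 if kind == "BLOSUM flag" else 0.0)

    b = total(penalties.blosum_flag, "BLOSUM flag")
    return VariantReport(
        label=label or (mutation_list(variant, offset) or "wild type"),
        variant=variant,
        dot=dot_string(variant, wt),
        mutations=mutation_list(variant, offset),
        E=dict(E),
        B=int(b) if b is not None else None,
        C=total(penalties.conservation_penalty, "conservation"),
        ddg_total=total(penalties.ddg, "ddG"),
        S=S,
    )


# ---------------------------------------------------------------------------
# Elimination statistics
# ---------------------------------------------------------------------------


@dataclass
class EliminationStats:
    """How many predicted epitopes a variant removes relative to wild type."""

    deleted: int
    percent_reduction: float
    wildtype_total: int
    variant_total: int
    undefined: bool  # wild type had no epitopes to delete
    per_window: list[int] = field(default_factory=list)
    per_allele: dict[str, int] = field(default_factory=dict)
    epitopes_per_substitution: float | None = None


def elimination_stats(
    wt_profile: EpitopeProfile,
    var_profile: EpitopeProfile,
    n_substitutions: int | None = None,
) -> EliminationStats:
    """Per-window / per-allele epitope deltas between wild type and a variant."""
    if len(wt_profile.sequence) != len(var_profile.sequence):
        raise ValueError("profiles cover sequences of different length")
    if wt_profile.allele_ids != var_profile.allele_ids:
        raise ValueError("profiles cover different allele panels")
    e_wt, e_var = wt_profile.total, var_profile.total
    deleted = e_wt - e_var
    per_window = [
        len(hw) - len(hv) for hw, hv in zip(wt_profile.hits, var_profile.hits)
    ]
    per_allele = {
        aid: sum(
            (aid in hw) - (aid in hv)
            for hw, hv in zip(wt_profile.hits, var_profile.hits)
        )
        for aid in wt_profile.allele_ids
    }
    undefined = e_wt == 0
    pct = 0.0 if undefined else 100.0 * deleted / e_wt
    eps = None
    if n_substitutions:
        eps = deleted / n_substitutions
    return EliminationStats(
        deleted=deleted,
        percent_reduction=pct,
        wildtype_total=e_wt,
        variant_total=e_var,
        undefined=undefined,
        per_window=per_window,
        per_allele=per_allele,
        epitopes_per_substitution=eps,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ("variant", "dot_string", "mutations", "E10", "E5", "B", "C", "ddG", "S")


def write_report_tsv(
    reports: Iterable[VariantReport], fh: TextIO, percents: Sequence[int] = (10, 5)
) -> None:
    cols = ["variant", "dot_string", "mutations"] + [f"E{p}" for p in percents] + [
        "B",
        "C",
        "ddG",
        "S",
    ]
    fh.write("\t".join(cols) + "\n")
    for r in reports:
        row = r.row(percents)
        fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def write_report_json(
    reports: Iterable[VariantReport], fh: TextIO, percents: Sequence[int] = (10, 5), **meta
) -> None:
    payload = {"meta": meta, "variants": [r.row(percents) for r in reports]}
    json.dump(payload, fh, indent=2, sort_keys=True)
    fh.write("\n")


def write_profile_tsv(
    wt_profile: EpitopeProfile, var_profile: EpitopeProfile | None, fh: TextIO
) -> None:
    """Per-window counts behind the epitope-density profile plots."""
    fh.write("window_start\twt_count\tvariant_count\talleles_hit\n")
    for j in range(wt_profile.n_windows):
        wt_hits = wt_profile.hits[j]
        var_count = len(var_profile.hits[j]) if var_profile is not None else ""
        fh.write(
            f"{j + 1}\t{len(wt_hits)}\t{var_count}\t"
            + ",".join(sorted(wt_hits))
            + "\n"
        )


def write_allele_map_tsv(
    wt_profile: EpitopeProfile, var_profile: EpitopeProfile, fh: TextIO
) -> None:
    """Per-allele epitope extents and whether the variant eliminated each."""
    w = wt_profile.window
    fh.write("allele\twindow_start\twindow_end\teliminated\n")
    for aid in wt_profile.allele_ids:
        for j, hits in enumerate(wt_profile.hits):
            if aid in hits:
                gone = int(aid not in var_profile.hits[j])
                fh.write(f"{aid}\t{j + 1}\t{j + w}\t{gone}\n")
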
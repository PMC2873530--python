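"""Run configuration, input assembly, and the end-to-end design pipeline.

A run is declared in a single YAML file (or built programmatically); CLI
flags override individual fields.  Defaults follow the method's standard
settings: BLOSUM relative-score cutoff 4, conservation frequency floor 0.05,
ΔΔG° margin 0.25 kcal/mol, percent level 10.  Coordinates in all outputs are
1-based and inclusive, shifted by a user-supplied numbering offset so that a
fragment starting at residue 71 reports mutations like "V79T".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .design import (
    DesignProblem,
    InfeasibleError,
    PanelScorer,
    Variant,
    brute_force,
    build_tables,
    enumerate_near_optimal,
)
from .epitope import AllelePanel, scan_sequence
from .io import (
    InputError,
    load_ddg_table,
    load_panel,
    read_alignment_fasta,
    read_fasta_single,
    read_newick,
)
from .mutability import (
    AllowedResidues,
    PenaltyTables,
    blosum_allowed,
    conservation_allowed,
    foldx_allowed,
    weighted_alignment,
)
from .report import (
    VariantReport,
    evaluate_variant,
    write_allele_map_tsv,
    write_profile_tsv,
    write_report_json,
    write_report_tsv,
)

MUTABILITY_SOURCES = ("blosum", "conservation", "foldx")


@dataclass
class RunConfig:
    """Declarative description of one design run."""

    sequence: str = ""  # path to a single-record FASTA
    offset: int = 1
    matrices: str = ""  # path to a pocket-profile matrix TSV
    percent: int = 10
    report_percents: tuple[int, ...] = (10, 5)
    mutability: list[str] = field(default_factory=lambda: ["blosum"])
    max_diff: int = 4
    msa: str | None = None
    tree: str | None = None
    freq_min: float = 0.05
    ddg: str | None = None
    margin: float = 0.25
    budget: int | None = None
    budget_mode: str = "at_most"
    epsilon: int = 0
    limit: int = 50
    window_cap: bool = False
    seed: int = 0
    out_dir: str = "epidesign_out"

    def __post_init__(self) -> None:
        if isinstance(self.mutability, str):
            self.mutability = [self.mutability]
        unknown = [m for m in self.mutability if m not in MUTABILITY_SOURCES]
        if unknown:
            raise InputError(
                f"unknown mutability source(s) {unknown}; choose from {MUTABILITY_SOURCES}"
            )
        if not self.mutability:
            raise InputError("at least one mutability source is required")
        if not 1 <= self.percent <= 10:
            raise InputError(f"percent level must be in 1..10, got {self.percent}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a YAML mapping")
        known = set(cls.__dataclass_fields__)
        bad = sorted(set(data) - known)
        if bad:
            raise InputError(f"{path}: unknown config keys {bad}")
        if "report_percents" in data:
            data["report_percents"] = tuple(data["report_percents"])
        return cls(**data)


@dataclass
class LoadedInputs:
    config: RunConfig
    target_id: str
    wildtype: str
    panel: AllelePanel
    problem: DesignProblem
    M: AllowedResidues
    penalties: PenaltyTables
    warnings: list[str]


def load_inputs(config: RunConfig) -> LoadedInputs:
    """Read and cross-validate every input of a run into a DesignProblem."""
    target_id, seq = read_fasta_single(config.sequence)
    panel = load_panel(config.matrices, percent=config.percent)

    captured: list[str] = []
    M: AllowedResidues | None = None
    penalties = PenaltyTables()
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        for source in config.mutability:
            if source == "blosum":
                m_i, p_i = blosum_allowed(seq, max_diff=config.max_diff)
            elif source == "conservation":
                if not config.msa:
                    raise InputError("conservation mutability requires an 'msa' path")
                rows = read_alignment_fasta(config.msa)
                if target_id not in rows:
                    raise InputError(
                        f"{config.msa}: target record {target_id!r} not found in alignment"
                    )
                tree = read_newick(config.tree) if config.tree else None
                walign = weighted_alignment(rows, target_id, tree)
                if walign.target_sequence != seq:
                    raise InputError(
                        f"{config.msa}: ungapped target row differs from {config.sequence}"
                    )
                m_i, p_i = conservation_allowed(walign, freq_min=config.freq_min)
            else:  # foldx
                if not config.ddg:
                    raise InputError("foldx mutability requires a 'ddg' table path")
                table, wt_of = load_ddg_table(config.ddg)
                for pos, wt in wt_of.items():
                    if 1 <= pos <= len(seq) and seq[pos - 1] != wt:
                        raise InputError(
                            f"{config.ddg}: wild-type mismatch at position {pos}: "
                            f"table says {wt}, sequence has {seq[pos - 1]}"
                        )
                m_i, p_i = foldx_allowed(seq, table, margin=config.margin)
            M = m_i if M is None else M.intersect(m_i)
            penalties = penalties.merge(p_i)
        for w in wlist:
            captured.append(str(w.message))

    scorer = PanelScorer(panel, config.percent)
    problem = DesignProblem(
        sequence=seq,
        scorer=scorer,
        M=M,
        budget=config.budget,
        budget_mode=config.budget_mode,
        window_cap=config.window_cap,
    )
    return LoadedInputs(
        config=config,
        target_id=target_id,
        wildtype=seq,
        panel=panel,
        problem=problem,
        M=M,
        penalties=penalties,
        warnings=captured,
    )


def _manifest(inputs: LoadedInputs, extra: dict) -> dict:
    cfg = asdict(inputs.config)
    cfg["report_percents"] = list(inputs.config.report_percents)
    return {
        "tool": "epidesign",
        "version": __version__,
        "seed": inputs.config.seed,
        "target_id": inputs.target_id,
        "config": cfg,
        "warnings": inputs.warnings,
        **extra,
    }


def run_design(config: RunConfig) -> Path:
    """Optimize, enumerate near-optimal variants, and write the report bundle.

    Writes to ``config.out_dir``: ``report.tsv`` / ``report.json`` (ranked
    variants with metric columns), ``profile_wildtype.tsv``, a per-variant
    profile TSV and allele map for each reported variant, and
    ``manifest.json`` echoing the configuration.  Returns the output dir.
    """
    inputs = load_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    problem, panel = inputs.problem, inputs.panel

    status = "ok"
    try:
        variants = enumerate_near_optimal(
            problem, epsilon=config.epsilon, limit=config.limit
        )
    except InfeasibleError:
        variants = []
        status = "infeasible"

    wt_variant = problem.variant_from_sequence(inputs.wildtype)
    reports: list[VariantReport] = [
        evaluate_variant(
            wt_variant,
            panel,
            inputs.penalties,
            percents=config.report_percents,
            label="wild type",
            offset=config.offset,
            wildtype=inputs.wildtype,
        )
    ]
    for v in variants:
        reports.append(
            evaluate_variant(
                v,
                panel,
                inputs.penalties,
                percents=config.report_percents,
                offset=config.offset,
                wildtype=inputs.wildtype,
            )
        )

    wt_profile = scan_sequence(panel, inputs.wildtype, config.percent)
    with open(out / "profile_wildtype.tsv", "w") as fh:
        write_profile_tsv(wt_profile, None, fh)
    for rank, v in enumerate(variants, start=1):
        vp = scan_sequence(panel, v.sequence, config.percent)
        with open(out / f"variant_{rank:03d}_profile.tsv", "w") as fh:
            write_profile_tsv(wt_profile, vp, fh)
        with open(out / f"variant_{rank:03d}_allele_map.tsv", "w") as fh:
            write_allele_map_tsv(wt_profile, vp, fh)

    with open(out / "report.tsv", "w") as fh:
        write_report_tsv(reports, fh, percents=config.report_percents)
    with open(out / "report.json", "w") as fh:
        write_report_json(
            reports,
            fh,
            percents=config.report_percents,
            **_manifest(inputs, {"status": status, "n_variants": len(variants)}),
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            _manifest(inputs, {"status": status, "n_variants": len(variants)}),
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    if status == "infeasible":
        raise InfeasibleError(
            "no feasible variant under the requested budget; empty report written"
        )
    return out
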
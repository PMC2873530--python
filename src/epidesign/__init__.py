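"""epidesign: globally optimal T-cell epitope removal for protein deimmunization.

Score every 9-mer window of a protein for predicted MHC-II (HLA-DR) binding
with additive pocket-profile matrices, restrict each position to residues
deemed safe for stability/activity, and find provably optimal and
near-optimal substitution sets minimizing total predicted epitope content by
dynamic programming over 8-mer suffix states.
"""

__version__ = "0.1.0"

from importlib import resources

from .alphabet import AMINO_ACIDS
from .design import (
    BruteForceResult,
    DesignProblem,
    EnumerationGuardError,
    InfeasibleError,
    PanelScorer,
    Variant,
    brute_force,
    enumerate_near_optimal,
    optimize,
    optimize_budget,
)
from .epitope import (
    AllelePanel,
    EpitopeProfile,
    PocketProfileMatrix,
    calibrate_thresholds,
    recognition_histogram,
    scan_sequence,
    score_peptide,
)
from .mutability import (
    AllowedResidues,
    PenaltyTables,
    WeightedAlignment,
    blosum_allowed,
    conservation_allowed,
    count_variants,
    enumerate_variants,
    foldx_allowed,
    gsc_weights,
    weighted_alignment,
)
from .report import (
    VariantReport,
    dot_string,
    elimination_stats,
    evaluate_variant,
    mutation_list,
    parse_dot_string,
    parse_mutation_list,
)
from .run import RunConfig, load_inputs, run_design

#: Immunodominant staphylokinase fragment (SakSTAR residues 71-87), the
#: packaged worked example: a 17-residue peptide whose 9 windows carry a
#: dense cluster of predicted HLA-DR epitopes.
SAKSTAR_71_87 = "TAYKEFRVVELDPSAKI"
SAKSTAR_OFFSET = 71


def packaged_fixture_path(name: str = "sakstar_71_87.fasta"):
    """Path to a packaged plain-text fixture file."""
    return resources.files(__package__) / "data" / name
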
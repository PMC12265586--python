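"""foldpath — structural analysis of protein folding pathway intermediates.

Library for comparing (partial and full) 3D conformations of folding
intermediates with the TM-score, extracting "proxy" co-translational
intermediates from native structures, modelling structures as static and
dynamic protein structure networks with graphlet features, classifying
structures from those features, and computing folding-kinetics
statistics (contact order, two-state pathway fraction).  Synthetic
Cα-trace generators make every stage testable without downloads.
"""

from importlib import resources

from .structures import (
    Residue, Conformation, Pathway, Manifest,
    read_structure, write_structure, map_common_residues,
    read_manifest, write_manifest,
)
from .superpose import (
    SuperpositionResult, TMResult, kabsch_superpose, compute_d0,
    tm_score, similarity_band,
)
from .proxy import ProxySchedule, proxy_schedule, generate_proxy_intermediates, match_proxy
from .psn import (
    PSNParams, PSN, DynamicPSN, GraphletVector, GRAPHLET_NAMES,
    build_psn, build_dynamic_psn, count_graphlets,
    static_features, dynamic_features,
)
from .analyses import (
    ComparisonRecord, ContactOrderResult, KineticsReport,
    curate_manifest, compare_same_intermediate, compare_across_time,
    evaluate_predictions, evaluate_proxies, contact_order, two_state_stats,
)
from .classify import ClassificationReport, run_classification, compare_feature_modes
from . import synthetic

__version__ = "0.1.0"


def load_cotranslational_manifest() -> Manifest:
    """The packaged catalogue of experimentally determined
    co-translational intermediate conformations (4 studies, 11
    intermediates, 17 conformations, 2 excluded).

    The table is a synthetic reconstruction assembled from the published
    summary of those studies: study membership, deposited ranges of two
    studies, which entries have modeled ranges shorter than deposited,
    and which two are excluded are as published; remaining per-row
    ranges are placeholders.
    """
    with resources.as_file(
        resources.files("foldpath.data") / "fig3_manifest.tsv"
    ) as path:
        return read_manifest(path)
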
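"""phnmr — comparative structural-NMR analysis of the TFIIH PH domain.

Tools for working with NMR-derived protein structure ensembles and the
companion experiments used to characterize them: rigid-body (Kabsch)
superposition and region-restricted RMSD, ensemble coordinate precision,
region-restricted sequence identity, NOE distance-restraint binning,
chemical-shift-perturbation (CSP) mapping from HSQC titrations,
steady-state heteronuclear NOE mobility analysis, and single-site ITC
binding simulation and fitting.

Synthetic-data generators in :mod:`phnmr.synthetic` produce every input
class with known ground truth so the full pipeline runs without any
external depositions.
"""

from phnmr.exceptions import (
    CoverageError,
    ParseError,
    PhnmrError,
    RosterError,
    SelectionError,
)
from phnmr.structure_io import (
    AtomRecord,
    Selection,
    StructureEnsemble,
    extract_coordinates,
    read_ensemble,
    write_ensemble,
)
from phnmr.superpose import (
    EnsemblePrecision,
    RegionCorrespondence,
    Superposition,
    ensemble_precision,
    kabsch,
    region_rmsd,
)
from phnmr.seqid import AlignmentMap, SeqRecord, global_align, percent_identity
from phnmr.restraints import (
    BinningScheme,
    RestraintRecord,
    RestraintSummary,
    assign_bounds,
    classify_separation,
    summarize,
)
from phnmr.csp import (
    CspTable,
    Peak,
    TitrationSeries,
    call_perturbed,
    delta_delta,
    track_peaks,
)
from phnmr.hetnoe import HetNoeRecord, compute_noe, flag_mobile
from phnmr.itc import (
    BindingParams,
    ITCExperiment,
    OneSiteBindingModel,
    OneSiteFitResult,
    fit_single_site,
    simulate_isotherm,
    thermodynamics,
)

__version__ = "0.1.0"

__all__ = [
    "AtomRecord",
    "StructureEnsemble",
    "Selection",
    "read_ensemble",
    "write_ensemble",
    "extract_coordinates",
    "Superposition",
    "RegionCorrespondence",
    "EnsemblePrecision",
    "kabsch",
    "region_rmsd",
    "ensemble_precision",
    "SeqRecord",
    "AlignmentMap",
    "global_align",
    "percent_identity",
    "RestraintRecord",
    "BinningScheme",
    "RestraintSummary",
    "classify_separation",
    "assign_bounds",
    "summarize",
    "Peak",
    "TitrationSeries",
    "CspTable",
    "delta_delta",
    "track_peaks",
    "call_perturbed",
    "HetNoeRecord",
    "compute_noe",
    "flag_mobile",
    "ITCExperiment",
    "BindingParams",
    "OneSiteBindingModel",
    "OneSiteFitResult",
    "simulate_isotherm",
    "fit_single_site",
    "thermodynamics",
    "PhnmrError",
    "ParseError",
    "RosterError",
    "SelectionError",
    "CoverageError",
]
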
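"""vardyn: variant pathogenicity prediction from structural-dynamics descriptors.

Pipeline stages: exhaustive missense enumeration from a coding sequence,
ten-descriptor feature extraction from trajectories, evidence-based 4-way
class labeling, SMOTE balancing, and multiclass classifier training with
one-vs-rest ROC evaluation and decision-tree feature importance.
"""

from .balance import class_weights, resample, smote_balance
from .labeling import ClassLabel, EvidenceRecord, apply_labels, assign_label
from .models_eval import (
    EvaluationReport,
    ModelSpec,
    SuiteConfig,
    cross_validated_scores,
    default_model_specs,
    dt_feature_importance,
    fit_predict,
    metrics_report,
    roc_auc_ovr,
    run_benchmark_suite,
    stratified_folds,
    train_test_split,
)
from .seqvariants import (
    CodingSequence,
    EffectClass,
    MissenseVariant,
    classify_substitution,
    enumerate_missense,
    translate_codon,
    write_variant_fasta,
)
from .trajfeatures import (
    FEATURE_NAMES,
    AtomRecord,
    FeatureConfig,
    FeatureSeries,
    FeatureVector,
    Trajectory,
    assign_secondary_structure,
    count_contacts,
    count_hbonds,
    inertia_scalar,
    inertia_tensor,
    radius_of_gyration,
    sasa_shrake_rupley,
    select_stable_window,
    stability_surrogate,
    summarize_features,
    superpose_rmsd,
    zscore_scale,
)

__version__ = "0.1.0"
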
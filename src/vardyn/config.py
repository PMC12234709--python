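"""Pipeline configuration: all stage defaults in one validated object."""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict


class PipelineConfig(BaseModel):
    """Effective configuration of a pipeline run.

    Unknown keys are rejected; the full effective config is echoed into the
    run manifest so deterministic stages reproduce bit-for-bit.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    # enumeration
    dedupe_protein: bool = True
    include_start_codon: bool = False
    # descriptors
    sasa_probe: float = 1.4
    sasa_points: int = 960
    contact_cutoff: float = 5.0
    contact_min_seq_separation: int = 3
    hbond_dist_cutoff: float = 3.5
    hbond_angle_cutoff: float = 120.0
    window_fraction: float = 0.25
    window_alpha: float = 0.75
    window_majority_fraction: float = 0.7
    # labeling
    disease_model: str = "recessive_early_onset"
    af_threshold: float = 1e-4
    # balancing
    smote_k: int = 5
    # modelling protocol
    protocol: str = "leakage_safe"  # or "paper_compat"
    test_fraction: float = 0.2
    split_seed: int = 42
    n_folds: int = 10
    external_default_threshold: float = 0.5
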
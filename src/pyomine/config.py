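"""Pipeline configuration: every gate and threshold in one serializable place.

Defaults are the operating points of the published pipeline; pHMM score gates
are re-calibratable per model because absolute bit scores depend on seed
alignments and background composition.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    # substrate decision rules
    substrate_threshold: float = 0.7  # JC feature distance, == 50% identity
    relative_difference: float = 0.2
    # receptor gates
    receptor_min_len: int = 750
    receptor_max_len: int = 850
    stn_gate: float = 25.0
    plug_gate: float = 50.0
    tonb_gate: float = 80.0
    r1_gate: float = 50.0
    r2_gate: float = 30.0
    # assembly-line QC
    edge_bp: int = 100
    # genome context
    pep_window_bp: int = 20000
    # grouping / dereplication identity thresholds (%)
    whole_gene_identity: float = 60.0
    feature_identity: float = 70.0
    dereplication_identity: float = 95.0
    # conservation
    conserved_decile: float = 0.10
    # clustering choices
    substrate_metric: str = "jukes_cantor"
    substrate_linkage: str = "ward"
    receptor_group_linkage: str = "single"
    # receptor candidate enumeration
    min_orf_aa: int = 700
    # misc
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
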
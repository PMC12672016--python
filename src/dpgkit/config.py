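"""Run configuration: input paths, analysis thresholds, seed."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass
class RunConfig:
    """Pipeline configuration with the study's default thresholds.

    Thresholds: |inter-TSS distance| < ``max_dist`` defines a pair;
    ``t_distant`` splits optimal from distant spacing; co-expression needs
    rho > ``rho_min`` and p < ``p_max`` per tissue, or rho > ``general_rho``
    in more than ``general_frac`` of tissues to be general; indels need
    AF >= ``af_min`` and length change >= ``len_min``; samples need
    RIN > ``rin_min`` and tissues more than ``min_tissue_n`` samples;
    proportion tests switch from Fisher to chi-squared above ``n_threshold``.
    """

    out_dir: str = "results"
    seed: int = 0
    # inputs (all optional; stages without inputs are skipped)
    annotation: str | None = None
    expression_tpm: str | None = None
    expression_meta: str | None = None
    signal_bedgraph: str | None = None
    indel_vcf: str | None = None
    alignments: list[str] = field(default_factory=list)
    species: dict[str, dict[str, str]] = field(default_factory=dict)
    hk_list: str | None = None
    # thresholds
    max_dist: int = 1000
    t_distant: int = 500
    rho_min: float = 0.8
    p_max: float = 0.05
    general_rho: float = 0.7
    general_frac: float = 0.7
    af_min: float = 0.005
    len_min: int = 2
    rin_min: float = 6.0
    min_tissue_n: int = 20
    n_threshold: int = 40
    profile_bins: int = 1000
    profile_flank: int = 500

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.max_dist > 0, "max_dist must be positive"),
            (0 < self.t_distant < self.max_dist, "t_distant must lie in (0, max_dist)"),
            (0 < self.rho_min <= 1, "rho_min must be in (0, 1]"),
            (0 < self.p_max < 1, "p_max must be in (0, 1)"),
            (0 < self.general_rho <= 1, "general_rho must be in (0, 1]"),
            (0 < self.general_frac < 1, "general_frac must be in (0, 1)"),
            (self.af_min >= 0, "af_min must be non-negative"),
            (self.len_min >= 1, "len_min must be at least 1"),
            (self.rin_min >= 0, "rin_min must be non-negative"),
            (self.min_tissue_n >= 0, "min_tissue_n must be non-negative"),
            (self.n_threshold >= 0, "n_threshold must be non-negative"),
            (self.profile_bins > 0, "profile_bins must be positive"),
            (self.profile_flank >= 0, "profile_flank must be non-negative"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
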
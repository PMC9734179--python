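"""Pipeline configuration.

Holds the study's fixed constants — q-value thresholds (0.005 for target
calling, 0.001 for motif-discovery input), the 1-kb replicate
reproducibility bound, the ±10-kb target window, the ±150-bp peak-center
flank, the {2 kb, 10 kb} upstream windows, the GAGA/GAG motif set and the
large-Kenyon-cell cluster ids {1, 2, 6, 7} — and round-trips through YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple, Union

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    q_max_targets: float = 0.005
    q_max_motif_input: float = 0.001
    reconcile_max_distance: int = 1000
    target_window: int = 10_000
    peak_window_flank: int = 150
    upstream_lengths: Tuple[int, ...] = (2_000, 10_000)
    motifs: Tuple[Tuple[str, str], ...] = (("GAGA", "GAGA"), ("GAG", "GAG"))
    lkc_clusters: Tuple[int, ...] = (1, 2, 6, 7)
    marker_min_frac: float = 0.1
    marker_min_effect: float = 0.25
    marker_alpha: float = 0.05
    marker_correction: str = "bonferroni"
    rank_top_n: int = 40
    report_top_n: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_max_targets", "q_max_motif_input"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.reconcile_max_distance < 0 or self.target_window < 0:
            raise ValueError("distances must be non-negative")
        if not 0 <= self.marker_alpha <= 1:
            raise ValueError(f"marker_alpha must be in [0, 1], got {self.marker_alpha}")
        self.upstream_lengths = tuple(int(x) for x in self.upstream_lengths)
        self.motifs = tuple((str(n), str(p)) for n, p in self.motifs)
        self.lkc_clusters = tuple(int(c) for c in self.lkc_clusters)

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["upstream_lengths"] = list(self.upstream_lengths)
        d["motifs"] = [list(m) for m in self.motifs]
        d["lkc_clusters"] = list(self.lkc_clusters)
        return d

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "motifs" in data:
            data["motifs"] = tuple(tuple(m) for m in data["motifs"])
        return cls(**data)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
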
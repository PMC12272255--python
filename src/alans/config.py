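"""Pipeline configuration and logging.

A single flat configuration object carries every analysis knob: the
family-wise error rate of the conjunction stage, the number of homotopic
pairs tested, the candidate cluster counts, the confidence level of the
centrality intervals, and the betweenness conventions.  Configurations
round-trip through flat YAML files; command-line flags override file values.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "get_logger", "log_stage"]

EDGE_LENGTH_RULES = ("reciprocal", "one_minus_r")
DISSIMILARITY_RULES = ("sqrt_half", "one_minus_r_squared")


@dataclass
class PipelineConfig:
    """Analysis-wide parameters.

    alpha_family
        Family-wise error rate shared by the conjunction and sign-test
        stages (default 0.05).
    n_pairs
        Number of homotopic pairs entering the Bonferroni correction of the
        conjunction stage (default 185).
    k_range
        Candidate cluster counts for the optimal-k vote (default 2..10).
    ci_level
        Confidence level of the centrality intervals (default 0.95).
    bc_normalized
        If True, betweenness carries the 1/((N-1)(N-2)) factor; hub calls
        are invariant to this choice.
    edge_length_rule
        How a positive correlation weight w becomes a shortest-path edge
        length: ``reciprocal`` (1/w, default) or ``one_minus_r`` (1-w).
    dissimilarity_rule
        ``sqrt_half`` for d = sqrt((1-r)/2) (default) or
        ``one_minus_r_squared`` for d = 1-r^2.
    rng_seed
        Single seed from which every stage derives its random stream.
    """

    alpha_family: float = 0.05
    n_pairs: int = 185
    k_range: tuple[int, ...] = tuple(range(2, 11))
    ci_level: float = 0.95
    bc_normalized: bool = False
    edge_length_rule: str = "reciprocal"
    dissimilarity_rule: str = "sqrt_half"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_family < 1.0:
            raise ValueError("alpha_family must lie strictly between 0 and 1")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        self.k_range = tuple(int(k) for k in self.k_range)
        if not self.k_range or min(self.k_range) < 2:
            raise ValueError("k_range must be non-empty with every k >= 2")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie strictly between 0 and 1")
        if self.edge_length_rule not in EDGE_LENGTH_RULES:
            raise ValueError(f"edge_length_rule must be one of {EDGE_LENGTH_RULES}")
        if self.dissimilarity_rule not in DISSIMILARITY_RULES:
            raise ValueError(f"dissimilarity_rule must be one of {DISSIMILARITY_RULES}")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["k_range"] = list(self.k_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def get_logger(log_file: str | Path | None = None) -> logging.Logger:
    """Package logger writing one line per stage to stderr (and a file)."""
    logger = logging.getLogger("alans")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        logger.addHandler(fh)
    return logger


def log_stage(stage: str, **params) -> None:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    get_logger().info("stage=%s %s", stage, kv)
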
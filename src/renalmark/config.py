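"""Pipeline configuration: thresholds and run options.

The cutoffs collected here drive every calling stage: serum-protein
ratio calls (1.5-fold up / 0.67-fold down against the healthy-control
reference channel), tissue differential expression (2-fold change at
P <= 0.01), and the enrichment alpha for miRNA/mRNA functional pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraints."""


@dataclass
class PipelineConfig:
    """Thresholds and options shared across pipeline stages.

    Parameters
    ----------
    protein_up_cutoff : float
        Reporter-ion ratio at or above which a serum protein is called
        upregulated (default 1.5).
    protein_down_cutoff : float
        Ratio at or below which a protein is called downregulated
        (default 0.67). Must satisfy 0 < down < 1 < up.
    gene_fc_cutoff : float
        Fold-change threshold for tissue gene/miRNA differential
        expression (default 2.0, applied symmetrically as >= fc or
        <= 1/fc).
    gene_p_cutoff : float
        P-value threshold for the differential-expression test
        (default 0.01).
    mirna_direction : str
        Which anti-correlation layout the functional-pair stage tests:
        ``"down-vs-up"`` pairs downregulated miRNA families with
        upregulated genes; ``"up-vs-down"`` the reverse.
    enrichment_alpha : float
        Raw hypergeometric p-value threshold for reporting a family in
        the functional-pair analysis (default 0.05).
    de_method : str
        Differential-expression test: ``"welch"`` (Welch t on
        log2(x+1), default) or ``"mannwhitney"``.
    ratio_average : str
        How per-run reporter ratios are combined across label-swapped
        runs: ``"arithmetic"`` (default) or ``"geometric"``.
    rng_seed : int
        Seed recorded in run reports and used for any stage that
        draws random numbers (permutation tests, generators).
    """

    protein_up_cutoff: float = 1.5
    protein_down_cutoff: float = 0.67
    gene_fc_cutoff: float = 2.0
    gene_p_cutoff: float = 0.01
    mirna_direction: str = "down-vs-up"
    enrichment_alpha: float = 0.05
    de_method: str = "welch"
    ratio_average: str = "arithmetic"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.protein_down_cutoff < 1 < self.protein_up_cutoff):
            raise ConfigError(
                "protein cutoffs must satisfy 0 < protein_down_cutoff < 1 "
                f"< protein_up_cutoff; got protein_down_cutoff="
                f"{self.protein_down_cutoff}, protein_up_cutoff={self.protein_up_cutoff}"
            )
        if not 0 < self.gene_p_cutoff < 1:
            raise ConfigError(f"gene_p_cutoff must lie in (0, 1); got {self.gene_p_cutoff}")
        if self.gene_fc_cutoff <= 0:
            raise ConfigError(f"gene_fc_cutoff must be positive; got {self.gene_fc_cutoff}")
        if not 0 < self.enrichment_alpha <= 1:
            raise ConfigError(f"enrichment_alpha must lie in (0, 1]; got {self.enrichment_alpha}")
        if self.mirna_direction not in ("down-vs-up", "up-vs-down"):
            raise ConfigError(f"mirna_direction must be 'down-vs-up' or 'up-vs-down'; got {self.mirna_direction!r}")
        if self.de_method not in ("welch", "mannwhitney"):
            raise ConfigError(f"de_method must be 'welch' or 'mannwhitney'; got {self.de_method!r}")
        if self.ratio_average not in ("arithmetic", "geometric"):
            raise ConfigError(f"ratio_average must be 'arithmetic' or 'geometric'; got {self.ratio_average!r}")


def load_config(path) -> PipelineConfig:
    """Read a YAML config file, applying defaults for absent keys.

    An empty file yields all defaults. Unknown keys raise
    :class:`ConfigError` naming the key; invariant violations raise
    :class:`ConfigError` naming the offending key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a key-value mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return PipelineConfig(**raw)
    except ConfigError:
        raise


def save_config(config: PipelineConfig, path) -> None:
    """Serialize a config to YAML so load_config round-trips it."""
    data = {f.name: getattr(config, f.name) for f in fields(PipelineConfig)}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
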
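"""iTRAQ reporter-ion relative quantification.

Four pooled serum groups are multiplexed per run: R (clear-cell
carcinoma), C (benign renal mass), M (other urological tumors) and
H (healthy controls, the internal reference). Two runs with swapped
channel labelling control for label bias. The pipeline entry point is
the protein-level reporter intensity table; quantification proceeds:

1. median-ratio normalization of each channel to the reference
   channel (the channel carrying group H),
2. per-run comparison ratios R:H, R:C, R:M from the normalized
   channel intensities,
3. averaging of the per-run ratios across the two label-swapped runs
   (arithmetic mean by default),
4. threshold calls: up at ratio >= 1.5, down at <= 0.67 (inclusive),
   and a protein is carcinoma-upregulated when up in all three
   comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "ReporterRunTable",
    "ProteinRatioRecord",
    "normalize_run",
    "protein_ratios",
    "call_de_proteins",
    "COMPARISONS",
]

GROUPS = ("R", "C", "M", "H")
REFERENCE_GROUP = "H"
#: the three comparisons quantified per protein, all against group R
COMPARISONS = (("R", "H"), ("R", "C"), ("R", "M"))


@dataclass
class ReporterRunTable:
    """Protein x channel reporter intensities for one multiplexed run.

    intensities: DataFrame indexed by protein accession, one column
    per channel label (e.g. "114".."117"), strictly positive.
    channel_to_group must be a bijection onto {R, C, M, H}; the
    reference channel is the one carrying group H.
    """

    run_id: str
    intensities: pd.DataFrame
    channel_to_group: dict
    gene_symbols: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        chans = list(map(str, self.intensities.columns))
        self.intensities.columns = chans
        self.channel_to_group = {str(k): v for k, v in self.channel_to_group.items()}
        if set(self.channel_to_group) != set(chans):
            raise ValueError(
                f"run {self.run_id}: channel map keys {sorted(self.channel_to_group)} "
                f"do not match table channels {sorted(chans)}"
            )
        if sorted(self.channel_to_group.values()) != sorted(GROUPS):
            raise ValueError(
                f"run {self.run_id}: channel map must be a bijection onto {GROUPS}"
            )
        bad = np.argwhere(self.intensities.values <= 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"run {self.run_id}: non-positive intensity for protein "
                f"{self.intensities.index[i]!r} channel {chans[j]}"
            )

    @property
    def reference_channel(self) -> str:
        return self.channel_for_group(REFERENCE_GROUP)

    def channel_for_group(self, group: str) -> str:
        for ch, g in self.channel_to_group.items():
            if g == group:
                return ch
        raise KeyError(f"run {self.run_id}: no channel labelled with group {group!r}")

    @property
    def proteins(self) -> list:
        return list(self.intensities.index)


def normalize_run(table: ReporterRunTable) -> ReporterRunTable:
    """Median-ratio normalization of every channel to the reference channel.

    Each channel is rescaled so that the median across proteins of its
    ratio to the reference channel equals 1; the reference channel is
    untouched. This cancels per-channel labelling/loading efficiency
    while leaving protein-specific ratios intact, and is idempotent.
    """
    ref = table.reference_channel
    vals = table.intensities.copy()
    ref_col = vals[ref].to_numpy()
    for ch in vals.columns:
        scale = float(np.median(vals[ch].to_numpy() / ref_col))
        vals[ch] = vals[ch] / scale
    return ReporterRunTable(
        run_id=table.run_id,
        intensities=vals,
        channel_to_group=dict(table.channel_to_group),
        gene_symbols=dict(table.gene_symbols),
    )


@dataclass
class ProteinRatioRecord:
    """Averaged comparison ratios for one protein, with per-run detail."""

    protein: str
    gene: str
    ratio_RH: float
    ratio_RC: float
    ratio_RM: float
    per_run: dict  # run_id -> (R:H, R:C, R:M)
    runs_present: int = 2
    calls: dict = field(default_factory=dict)  # comparison -> up/down/unchanged
    rcc_upregulated: bool = False
    rcc_downregulated: bool = False

    def ratio(self, comparison: tuple[str, str]) -> float:
        return {("R", "H"): self.ratio_RH, ("R", "C"): self.ratio_RC,
                ("R", "M"): self.ratio_RM}[comparison]


def _run_ratios(table: ReporterRunTable) -> pd.DataFrame:
    cols = {}
    for x, y in COMPARISONS:
        cx = table.channel_for_group(x)
        cy = table.channel_for_group(y)
        cols[f"{x}:{y}"] = table.intensities[cx] / table.intensities[cy]
    return pd.DataFrame(cols)


def protein_ratios(
    run1: ReporterRunTable,
    run2: ReporterRunTable,
    average: str = "arithmetic",
) -> list[ProteinRatioRecord]:
    """Combine per-run comparison ratios across two label-swapped runs.

    Per run, ratio X:Y is the normalized intensity of group X's
    channel over group Y's. The record stores both per-run triples and
    their mean (arithmetic by default, geometric optionally). Proteins
    quantified in only one run are carried with their single-run
    values and runs_present = 1.
    """
    if average not in ("arithmetic", "geometric"):
        raise ValueError(f"average must be 'arithmetic' or 'geometric'; got {average!r}")
    r1 = _run_ratios(run1)
    r2 = _run_ratios(run2)
    records = []
    proteins = list(dict.fromkeys(list(r1.index) + list(r2.index)))
    for prot in proteins:
        per_run = {}
        if prot in r1.index:
            per_run[run1.run_id] = tuple(float(v) for v in r1.loc[prot])
        if prot in r2.index:
            per_run[run2.run_id] = tuple(float(v) for v in r2.loc[prot])
        stacked = np.array(list(per_run.values()))
        if average == "arithmetic":
            avg = stacked.mean(axis=0)
        else:
            avg = np.exp(np.log(stacked).mean(axis=0))
        gene = run1.gene_symbols.get(prot) or run2.gene_symbols.get(prot) or str(prot)
        records.append(
            ProteinRatioRecord(
                protein=str(prot),
                gene=gene,
                ratio_RH=float(avg[0]),
                ratio_RC=float(avg[1]),
                ratio_RM=float(avg[2]),
                per_run=per_run,
                runs_present=len(per_run),
            )
        )
    return records


def _call(ratio: float, config: PipelineConfig) -> str:
    if ratio >= config.protein_up_cutoff:
        return "up"
    if ratio <= config.protein_down_cutoff:
        return "down"
    return "unchanged"


def call_de_proteins(
    records: list[ProteinRatioRecord], config: PipelineConfig | None = None
) -> list[ProteinRatioRecord]:
    """Attach threshold calls (inclusive cutoffs) to each comparison.

    A protein is flagged carcinoma-upregulated (or -downregulated)
    when the call is up (down) in all three of R:H, R:C, R:M.
    """
    config = config or PipelineConfig()
    for rec in records:
        rec.calls = {
            "R:H": _call(rec.ratio_RH, config),
            "R:C": _call(rec.ratio_RC, config),
            "R:M": _call(rec.ratio_RM, config),
        }
        rec.rcc_upregulated = all(c == "up" for c in rec.calls.values())
        rec.rcc_downregulated = all(c == "down" for c in rec.calls.values())
    return records


def records_to_frame(records: list[ProteinRatioRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [r.protein for r in records],
            "gene": [r.gene for r in records],
            "ratio_RH": [r.ratio_RH for r in records],
            "ratio_RC": [r.ratio_RC for r in records],
            "ratio_RM": [r.ratio_RM for r in records],
            "runs_present": [r.runs_present for r in records],
            "call_RH": [r.calls.get("R:H", "") for r in records],
            "call_RC": [r.calls.get("R:C", "") for r in records],
            "call_RM": [r.calls.get("R:M", "") for r in records],
            "rcc_upregulated": [r.rcc_upregulated for r in records],
        }
    )
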
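"""Configuration objects for graph construction and flow decomposition."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class GraphConfig:
    """Knobs for splice-graph construction.

    Attributes
    ----------
    min_intron : int
        Deletions (CIGAR ``D``) shorter than this are absorbed into the
        flanking aligned block; ``N`` gaps always open a new block.  Introns
        shorter than ~20 bp are vanishingly rare, so shorter reference gaps
        are treated as small indels rather than splice events.
    small_gap : int
        Adjacent exon regions separated by at most this many uncovered bases
        are merged unconditionally (absent an intervening splice site): such
        a short gap is almost certainly an uncovered stretch of one exon,
        not an intron.
    moderate_gap : int
        Gap size up to which two regions are merged when both are highly
        covered (see ``high_cov``).
    high_cov : float
        Mean per-base depth both regions must reach for the moderate-gap
        merge.
    min_junction_support : int
        Minimum number of split alignments required to call a splice
        junction.  1 keeps every observed junction (max-sensitivity);
        raising it trades sensitivity for fewer false edges.
    """

    min_intron: int = 20
    small_gap: int = 10
    moderate_gap: int = 50
    high_cov: float = 20.0
    min_junction_support: int = 1


@dataclass
class FlowConfig:
    """Knobs for sparse flow decomposition.

    trials
        Number of independent random reweighting draws per node; the
        sparsest resulting flow is kept.
    seed
        Base seed for the reweighting RNG; fixed seed + fixed input gives
        byte-identical output.
    rel_eps / abs_eps
        Thresholding: a local flow entry below
        ``max(abs_eps, rel_eps * total_in_weight)`` is zeroed (marginals are
        then restored), removing LP noise and near-degenerate splits.
    min_tx_len / min_tx_weight
        Reported-transcript filters (bases / read-count flow).  Setting both
        to 0 is the max-sensitivity operating point.
    balance_tol
        Relative in/out weight imbalance at a node below which the smaller
        side is rescaled; larger imbalances get an auxiliary sentinel edge
        carrying the surplus.  Junction-support counts at typical depth
        fluctuate by 5-15% per side, so the default (0.5) treats anything
        under a ~1.5x discrepancy as counting noise and reserves sentinel
        edges for genuinely unexplained flow.
    """

    trials: int = 5
    seed: int = 0
    rel_eps: float = 0.01
    abs_eps: float = 1e-6
    min_tx_len: int = 200
    min_tx_weight: float = 1.0
    balance_tol: float = 0.5


@dataclass
class RunConfig:
    """Full assembler configuration: graph + flow knobs plus run plumbing."""

    graph: GraphConfig = field(default_factory=GraphConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    processes: int = 1
    chromosome: str | None = None

    @classmethod
    def max_sensitivity(cls) -> "RunConfig":
        """Preset reporting every decomposed path (no length/weight filter)."""
        cfg = cls()
        cfg.graph.min_junction_support = 1
        cfg.flow.min_tx_len = 0
        cfg.flow.min_tx_weight = 0.0
        return cfg

    def apply_overrides(self, overrides: dict[str, str]) -> None:
        """Apply flat ``key=value`` overrides (e.g. from a config file)."""
        for key, raw in overrides.items():
            target = None
            for section in (self.graph, self.flow):
                if key in {f.name for f in dataclasses.fields(section)}:
                    target = section
                    break
            if target is None:
                if key in {f.name for f in dataclasses.fields(self)}:
                    target = self
                else:
                    raise KeyError(f"unknown config key: {key}")
            current = getattr(target, key)
            caster = type(current) if current is not None else str
            setattr(target, key, caster(raw))


def load_config_file(path: str | Path) -> dict[str, str]:
    """Read a flat ``key=value`` config file (blank lines and # comments ok)."""
    overrides: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        overrides[key.strip()] = value.strip()
    return overrides
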
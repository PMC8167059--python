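"""Remove low-confidence residues (plus flanking neighbors) from a model.

Residues scoring below the threshold (0.9 by default) are removed together
with the preceding and following residues of the same chain — a mistraced
residue usually drags its neighbors' geometry with it — producing a model
suitable for the next round of automated building, where the gaps can be
rebuilt or extended.  "Preceding/following" means adjacency in the chain's
file-order residue list (robust to insertion codes and numbering gaps);
adjacency never crosses chains, and chain ends truncate the window.
Ligands and waters below the threshold are removed without flanking.
Unscored residues are always retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model_io import Chain, Model
from .scoring import ResidueScore

logger = logging.getLogger(__name__)

__all__ = ["PruneConfig", "PruneReport", "RemovedResidue", "prune", "write_removed_list"]


@dataclass(frozen=True)
class PruneConfig:
    """threshold: score cutoff τ (default 0.9); flank: neighbors removed on
    each side of every sub-threshold polymer residue (default 1)."""

    threshold: float = 0.9
    flank: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass(frozen=True)
class RemovedResidue:
    chain_id: str
    number: int
    insertion_code: str
    name: str
    score: float | None
    reason: str  # below_threshold | flanking

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)


@dataclass
class PruneReport:
    removed: list[RemovedResidue] = field(default_factory=list)
    retained_per_chain: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def prune(
    model: Model, scores: list[ResidueScore], config: PruneConfig | None = None
) -> tuple[Model, PruneReport]:
    """Prune a model; returns (pruned copy, report). Never mutates the input."""
    config = config or PruneConfig()
    score_by_id: dict[tuple[str, int, str], float | None] = {
        s.residue_id: s.score for s in scores
    }

    pruned = Model(chains=[], format=model.format, name=model.name)
    report = PruneReport()
    for chain in model.chains:
        residues = chain.residues
        below: set[int] = set()
        remove: set[int] = set()
        for i, res in enumerate(residues):
            score = score_by_id.get(res.id)
            if score is None or score >= config.threshold:
                continue
            below.add(i)
            remove.add(i)
            if res.category in ("protein", "nucleic"):
                lo = max(i - config.flank, 0)
                hi = min(i + config.flank, len(residues) - 1)
                remove.update(range(lo, hi + 1))
        kept = []
        for i, res in enumerate(residues):
            if i in remove:
                report.removed.append(
                    RemovedResidue(
                        chain_id=res.chain_id,
                        number=res.number,
                        insertion_code=res.insertion_code,
                        name=res.name,
                        score=score_by_id.get(res.id),
                        reason="below_threshold" if i in below else "flanking",
                    )
                )
            else:
                kept.append(res)
        report.retained_per_chain[chain.id] = len(kept)
        if kept:
            pruned.chains.append(Chain(chain.id, [r for r in kept]))
    if report.n_removed:
        logger.info(
            "pruned %d residues at threshold %.2f (flank %d)",
            report.n_removed,
            config.threshold,
            config.flank,
        )
    return pruned.copy(), report


def write_removed_list(report: PruneReport, path) -> None:
    """Plain-text removal list: chain, number+icode, name, score, reason."""
    with open(path, "w") as fh:
        fh.write("# chain\tresidue\tname\tscore\treason\n")
        for r in report.removed:
            score = "" if r.score is None else f"{r.score:.3f}"
            fh.write(f"{r.chain_id}\t{r.number}{r.insertion_code}\t{r.name}\t{score}\t{r.reason}\n")
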
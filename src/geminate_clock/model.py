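"""Model/Results facade over the calibration pipeline.

`GeminateDivergenceModel` holds the study design — per-locus
alignments, the sample-to-clade partition, the biogeographic
calibration date — and `fit()` runs distance estimation, divergence
summaries, rate calibration, the haplotype network, barcode-gap
delimitation and the clock test, returning a
`GeminateDivergenceResults` with a printable `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from ._format import fmt_percent
from .alignment import Alignment, GroupPartition, read_alignment, read_partition, trim_alignment
from .calibration import RateEstimate, TblRatio, mu_ratio, rate_table, total_branch_length
from .clock import ClockTestResult, clock_lrt
from .delimitation import PartitionResult, barcode_gap_partition
from .distances import (
    DistanceMatrix,
    DivergenceSummary,
    mcl_distances,
    p_distances,
    summarize_divergence,
    tn93_distances,
)
from .errors import ConfigError, PartitionError
from .network import HaplotypeNetwork, annotate_by_group, build_msn, collapse_haplotypes
from .trees import nj_tree, parse_newick

_MITO_NAMES = {"coi", "cox1", "co1", "16s", "12s", "cytb", "nd1", "nd4"}

_ESTIMATORS = {"p": p_distances, "tn93": tn93_distances, "mcl": mcl_distances}


@dataclass
class GeminateDivergenceModel:
    """Multi-locus geminate-pair divergence-rate model.

    Parameters
    ----------
    alignments:
        Locus name -> aligned sequences (outgroups may be included;
        they are excluded from divergence statistics but retained for
        tree rooting in the clock test).
    partition:
        Sample -> (group, region) labels. The two ``geminate_groups``
        are the clades on either side of the barrier.
    calibration_myr:
        Age of the vicariant split (default 2.8, the Isthmus closure).
    distance_model:
        "mcl" (composite-likelihood TN93, default), "tn93" or "p".
    trees:
        Optional locus -> Newick/Tree used for total branch lengths and
        as the fixed clock-test topology; loci without a tree fall back
        to neighbor joining.
    """

    alignments: Mapping[str, Alignment]
    partition: GroupPartition
    geminate_groups: tuple[str, str] | None = None
    calibration_myr: float = 2.8
    distance_model: str = "mcl"
    mito_loci: Sequence[str] | None = None
    nuclear_loci: Sequence[str] | None = None
    trees: Mapping[str, "str | dendropy.Tree"] = field(default_factory=dict)
    outgroups: Sequence[str] = ()
    trim_windows: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    network_locus: str | None = None
    delimit_locus: str | None = None
    use_mean_divergence: bool = False
    gamma_categories: int = 4
    seed: int = 0

    def __post_init__(self):
        if not self.alignments:
            raise ConfigError("no alignments supplied")
        self.alignments = dict(self.alignments)
        if self.distance_model not in _ESTIMATORS:
            raise ConfigError(f"unknown distance model {self.distance_model!r}")
        if self.geminate_groups is None:
            groups = self.partition.groups
            if len(groups) < 2:
                raise ConfigError("partition must define at least two groups")
            self.geminate_groups = (groups[0], groups[1])
        for g in self.geminate_groups:
            if g not in self.partition.groups:
                raise ConfigError(f"geminate group {g!r} not present in partition")
        loci = list(self.alignments)
        if self.mito_loci is None:
            self.mito_loci = [l for l in loci if l.lower() in _MITO_NAMES]
        if self.nuclear_loci is None:
            self.nuclear_loci = [l for l in loci if l not in set(self.mito_loci)]
        self.network_locus = self.network_locus or loci[0]
        self.delimit_locus = self.delimit_locus or loci[0]
        self.trees = {
            k: (parse_newick(v) if isinstance(v, str) else v)
            for k, v in dict(self.trees).items()
        }

    @classmethod
    def from_files(
        cls,
        locus_fastas: Mapping[str, str | Path],
        partition_path: str | Path,
        tree_paths: Mapping[str, str | Path] | None = None,
        **kwargs,
    ) -> "GeminateDivergenceModel":
        alignments = {
            locus: read_alignment(path, locus) for locus, path in locus_fastas.items()
        }
        trees = {}
        for locus, path in (tree_paths or {}).items():
            trees[locus] = parse_newick(Path(path).read_text())
        return cls(alignments, read_partition(partition_path), trees=trees, **kwargs)

    # -----------------------------------------------------------------
    def _ingroup(self, aln: Alignment) -> Alignment:
        """Samples belonging to the geminate groups, outgroups dropped."""
        out = set(self.outgroups)
        keep = []
        for sid in aln.ids:
            if sid in out:
                continue
            if sid not in self.partition:
                raise PartitionError(f"sample {sid!r} has no group assignment")
            if self.partition.group(sid) in self.geminate_groups:
                keep.append(sid)
        if len(keep) < 2:
            raise ConfigError(f"{aln.locus}: fewer than 2 ingroup samples")
        return aln.subset(keep)

    def fit(
        self,
        *,
        run_clock_test: bool = True,
        run_network: bool = True,
        run_delimitation: bool = True,
    ) -> "GeminateDivergenceResults":
        estimator = _ESTIMATORS[self.distance_model]
        matrices: dict[str, DistanceMatrix] = {}
        summaries: dict[str, DivergenceSummary] = {}
        estimates: list[RateEstimate] = []
        g1, g2 = self.geminate_groups
        for locus, aln in self.alignments.items():
            ingroup = self._ingroup(aln)
            dm = estimator(ingroup)
            matrices[locus] = dm
            summary = summarize_divergence(dm, self.partition)
            summaries[locus] = summary
            mean, dmin, _ = summary.between[
                (g1, g2) if (g1, g2) in summary.between else (g2, g1)
            ]
            d_cal = mean if self.use_mean_divergence else dmin
            estimates.append(
                RateEstimate.from_divergence(locus, d_cal, self.calibration_myr)
            )

        tbl_ratio = None
        tbls: dict[str, float] = {}
        if self.mito_loci and self.nuclear_loci:
            for locus in list(self.mito_loci) + list(self.nuclear_loci):
                if locus not in self.alignments:
                    raise ConfigError(f"locus {locus!r} has no alignment")
                if locus in self.trees:
                    tbls[locus] = total_branch_length(self.trees[locus])
                else:
                    tbls[locus] = total_branch_length(nj_tree(matrices[locus]))
            tbl_ratio = mu_ratio(
                [(l, tbls[l]) for l in self.mito_loci],
                [(l, tbls[l]) for l in self.nuclear_loci],
            )

        network = None
        haplotype_counts: dict[str, int] = {}
        if run_network:
            aln = self._ingroup(self.alignments[self.network_locus])
            if self.network_locus in self.trim_windows:
                start, end = self.trim_windows[self.network_locus]
                aln = trim_alignment(aln, start, end)
            haps = collapse_haplotypes(aln)
            network = build_msn(haps, annotate_by_group(haps, self.partition))
            for group in self.geminate_groups:
                members = set(self.partition.members(group))
                haplotype_counts[group] = sum(
                    1 for h in haps if members & set(h.members)
                )

        delimitation = None
        if run_delimitation:
            delimitation = barcode_gap_partition(matrices[self.delimit_locus])

        clock_results: dict[str, ClockTestResult] = {}
        if run_clock_test:
            for locus, aln in self.alignments.items():
                present = set(aln.ids)
                og = next((o for o in self.outgroups if o in present), None)
                topology = self.trees.get(locus)
                clock_results[locus] = clock_lrt(
                    aln,
                    topology,
                    outgroup=og,
                    gamma_categories=self.gamma_categories,
                    seed=self.seed,
                )

        return GeminateDivergenceResults(
            model=self,
            distance_matrices=matrices,
            divergence_summaries=summaries,
            rate_estimates=estimates,
            tbl_ratio=tbl_ratio,
            tbls=tbls,
            network=network,
            haplotype_counts=haplotype_counts,
            delimitation=delimitation,
            clock_results=clock_results,
        )


@dataclass(frozen=True)
class GeminateDivergenceResults:
    """Fitted estimates, summaries and diagnostics of the pipeline."""

    model: GeminateDivergenceModel
    distance_matrices: Mapping[str, DistanceMatrix]
    divergence_summaries: Mapping[str, DivergenceSummary]
    rate_estimates: Sequence[RateEstimate]
    tbl_ratio: TblRatio | None
    tbls: Mapping[str, float]
    network: HaplotypeNetwork | None
    haplotype_counts: Mapping[str, int]
    delimitation: PartitionResult | None
    clock_results: Mapping[str, ClockTestResult]

    @property
    def rate_table(self) -> pd.DataFrame:
        return rate_table(self.rate_estimates, self.tbl_ratio)

    def rate_estimate(self, locus: str) -> RateEstimate:
        for e in self.rate_estimates:
            if e.locus == locus:
                return e
        raise KeyError(locus)

    def summary(self) -> str:
        lines = []
        g1, g2 = self.model.geminate_groups
        lines.append("Geminate-pair divergence-rate calibration")
        lines.append("=" * 57)
        lines.append(
            f"groups: {g1} vs {g2}; calibration age: "
            f"{self.model.calibration_myr} Myr; distances: {self.model.distance_model}"
        )
        lines.append("")
        lines.append(
            f"{'locus':<8}{'d_min %':>9}{'diverg. %/Myr':>15}{'subst. %/Myr':>14}"
        )
        for e in self.rate_estimates:
            lines.append(
                f"{e.locus:<8}{fmt_percent(e.d_min):>9}"
                f"{e.divergence_rate_percent:>15.1f}{e.substitution_rate_percent:>14.1f}"
            )
        if self.tbl_ratio is not None:
            r = self.tbl_ratio
            lines.append("")
            lines.append(
                f"gene-tree TBLs: "
                + ", ".join(f"{l}={t:.4g}" for l, t in list(r.mito_tbls) + list(r.nuclear_tbls))
            )
            lines.append(
                f"mu_m/mu_n = {r.ratio:.2f} (mu_m={r.mu_m:.4g}, mu_n={r.mu_n:.4g})"
            )
        for locus, s in self.divergence_summaries.items():
            if s.overall_within_species:
                mean, lo, hi = s.overall_within_species
                lines.append(
                    f"{locus}: overall divergence mean {fmt_percent(mean)}% "
                    f"(range {fmt_percent(lo)}%-{fmt_percent(hi)}%)"
                )
        if self.haplotype_counts:
            counts = ", ".join(f"{g}: {c}" for g, c in self.haplotype_counts.items())
            lines.append(f"unique haplotypes ({self.model.network_locus}): {counts}")
        if self.delimitation is not None:
            d = self.delimitation
            lines.append(
                f"barcode-gap clusters ({self.model.delimit_locus}): {d.n_clusters} "
                f"(threshold {fmt_percent(d.threshold)}%, gap {fmt_percent(d.gap_width)}%)"
            )
        for locus, c in self.clock_results.items():
            lines.append(
                f"clock test {locus}: 2dlnL={c.lr_stat:.3f}, df={c.df}, p={c.p_value:.2g}"
            )
        return "\n".join(lines)
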
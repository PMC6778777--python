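"""Sex-linked candidate discovery: presence/absence, zygosity, depth, saturation.

The inference rests on three expectations for a locus carried only on the
sex-limited chromosome of the heterogametic sex (W under ZW, Y under XY):

A. *presence/absence* — it is found in every individual of one sex and in
   none of the other;
B. *zygosity* — carriers are hemizygous, so no carrier may show more than
   one haplotype;
C. *depth* — carriers hold a single copy, so its read depth is about half
   that of a diploid locus (assessed on depth normalised by each carrier's
   median depth over non-candidate, putatively autosomal loci).

The three stages nest (depth ⊆ zygosity ⊆ presence per sex) and the whole
cascade is symmetric under relabelling the sexes.  The saturation analysis
re-runs stage A on nested subsets of individuals: spurious sex-specific
candidates — loci missing from a few individuals through uneven coverage or
catalog fragmentation — decay rapidly as individuals are added, while true
sex-limited loci persist.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assembly import CatalogLocus

VALID_SEXES = ("female", "male")


@dataclass
class PresenceMatrix:
    """Catalog locus x individual presence/zygosity/depth table.

    ``present``, ``haplotype_count`` and ``depth`` are aligned DataFrames
    indexed by catalog_id with one column per individual; ``sexes`` maps
    each individual to 'female' or 'male'.  Absent cells have depth 0 and
    haplotype count 0.
    """

    present: pd.DataFrame
    haplotype_count: pd.DataFrame
    depth: pd.DataFrame
    sexes: dict[str, str]

    def __post_init__(self) -> None:
        bad = {s for s in self.sexes.values()} - set(VALID_SEXES)
        if bad:
            raise ValueError(
                f"unknown sex label(s) {sorted(bad)}: sexes of individuals must be "
                "known with certainty for sex-linkage inference"
            )
        missing = set(self.present.columns) - set(self.sexes)
        if missing:
            raise ValueError(f"individuals without a sex label: {sorted(missing)}")

    @property
    def individuals(self) -> list[str]:
        return list(self.present.columns)

    def of_sex(self, sex: str) -> list[str]:
        return [i for i in self.individuals if self.sexes[i] == sex]

    def subset(self, individuals: Sequence[str]) -> "PresenceMatrix":
        cols = list(individuals)
        return PresenceMatrix(
            present=self.present[cols],
            haplotype_count=self.haplotype_count[cols],
            depth=self.depth[cols],
            sexes={i: self.sexes[i] for i in cols},
        )

    def relabel_sexes(self) -> "PresenceMatrix":
        """Swap every female label to male and vice versa (symmetry checks)."""
        flipped = {i: ("male" if s == "female" else "female") for i, s in self.sexes.items()}
        return PresenceMatrix(self.present, self.haplotype_count, self.depth, flipped)


def presence_matrix_from_catalog(
    catalog: Sequence[CatalogLocus],
    sexes: Mapping[str, str],
    min_presence_depth: int = 0,
    drop_excess_haplotype_loci: bool = True,
) -> PresenceMatrix:
    """Build the presence matrix from catalog loci and known sexes.

    Presence means the individual contributed a member locus (post assembly
    filters) with depth above ``min_presence_depth`` extra reads (default 0:
    any member counts).  Catalog loci for which any member shows more than
    two haplotypes are excluded from all further analysis when
    ``drop_excess_haplotype_loci`` is set.
    """
    individuals = sorted(sexes)
    kept = [
        c for c in catalog
        if not (drop_excess_haplotype_loci and any(len(m.alleles) > 2 for m in c.members.values()))
    ]
    index = [c.catalog_id for c in kept]
    present = pd.DataFrame(False, index=index, columns=individuals)
    hap = pd.DataFrame(0, index=index, columns=individuals)
    depth = pd.DataFrame(0, index=index, columns=individuals)
    for c in kept:
        for individual, locus in c.members.items():
            if individual not in sexes:
                raise ValueError(f"individual {individual} missing from the sample sheet")
            if locus.depth > min_presence_depth:
                present.loc[c.catalog_id, individual] = True
                hap.loc[c.catalog_id, individual] = locus.haplotype_count
                depth.loc[c.catalog_id, individual] = locus.depth
    return PresenceMatrix(present, hap, depth, dict(sexes))


def presence_matrix_from_matches(matches: pd.DataFrame, sexes: Mapping[str, str]) -> PresenceMatrix:
    """Rebuild a presence matrix from a matches TSV (catalog_id, individual,
    haplotype_count, depth)."""
    individuals = sorted(sexes)
    index = sorted(matches["catalog_id"].unique())
    present = pd.DataFrame(False, index=index, columns=individuals)
    hap = pd.DataFrame(0, index=index, columns=individuals)
    depth = pd.DataFrame(0, index=index, columns=individuals)
    for row in matches.itertuples(index=False):
        present.loc[row.catalog_id, row.individual] = True
        hap.loc[row.catalog_id, row.individual] = int(row.haplotype_count)
        depth.loc[row.catalog_id, row.individual] = int(row.depth)
    return PresenceMatrix(present, hap, depth, dict(sexes))


@dataclass(frozen=True)
class CandidateSet:
    """Candidate sex-specific loci after one stage of the cascade."""

    stage: str  # presence | zygosity | depth
    female_specific: tuple
    male_specific: tuple

    def counts(self) -> tuple[int, int]:
        return len(self.female_specific), len(self.male_specific)


def presence_absence_scan(matrix: PresenceMatrix, min_presence_frac: float = 1.0) -> CandidateSet:
    """Stage A: loci present in (all) individuals of one sex and no individual
    of the other.

    The default is the strict all/none rule.  ``min_presence_frac < 1``
    relaxes presence to a fraction of the carrying sex (absence in the other
    sex stays absolute) — useful when coverage is very uneven, at the cost
    of admitting more spurious candidates.
    """
    females = matrix.of_sex("female")
    males = matrix.of_sex("male")
    if not females or not males:
        raise ValueError("at least one individual of each sex is required")
    if not 0 < min_presence_frac <= 1:
        raise ValueError("min_presence_frac must lie in (0, 1]")
    p = matrix.present
    f_frac = p[females].mean(axis=1)
    m_frac = p[males].mean(axis=1)
    f_specific = p.index[(f_frac >= min_presence_frac) & (m_frac == 0)]
    m_specific = p.index[(m_frac >= min_presence_frac) & (f_frac == 0)]
    return CandidateSet("presence", tuple(f_specific), tuple(m_specific))


def zygosity_filter(candidates: CandidateSet, matrix: PresenceMatrix) -> CandidateSet:
    """Stage B: drop candidates where any individual of the carrying sex shows
    more than one haplotype (a hemizygous locus must look haploid)."""
    if candidates.stage != "presence":
        raise ValueError("zygosity_filter expects a presence-stage candidate set")

    def keep(loci: tuple, sex: str) -> tuple:
        cols = matrix.of_sex(sex)
        if not loci:
            return ()
        hap = matrix.haplotype_count.loc[list(loci), cols]
        ok = (hap <= 1).all(axis=1)
        return tuple(hap.index[ok])

    return CandidateSet(
        "zygosity",
        keep(candidates.female_specific, "female"),
        keep(candidates.male_specific, "male"),
    )


def normalization_depths(
    matrix: PresenceMatrix,
    candidate_ids: Sequence,
    min_autosomal_loci: int = 50,
) -> pd.Series:
    """Median depth per individual over non-candidate ("autosomal-candidate")
    loci present in that individual — the per-individual depth scale."""
    non_candidates = matrix.present.index.difference(pd.Index(candidate_ids))
    medians = {}
    for individual in matrix.individuals:
        mask = matrix.present.loc[non_candidates, individual]
        depths = matrix.depth.loc[non_candidates, individual][mask]
        if len(depths) < min_autosomal_loci:
            raise ValueError(
                f"individual {individual} has only {len(depths)} non-candidate loci "
                f"(need >= {min_autosomal_loci}) to estimate the autosomal depth scale"
            )
        medians[individual] = float(depths.median())
    return pd.Series(medians)


def carrier_depth_ratios(
    candidates: CandidateSet,
    matrix: PresenceMatrix,
    min_autosomal_loci: int = 50,
) -> pd.DataFrame:
    """Mean normalised depth over carriers for each candidate locus."""
    all_ids = list(candidates.female_specific) + list(candidates.male_specific)
    rows = []
    if all_ids:
        scale = normalization_depths(matrix, all_ids, min_autosomal_loci)
        for sex, loci in (("female", candidates.female_specific), ("male", candidates.male_specific)):
            carriers = matrix.of_sex(sex)
            for locus in loci:
                present = matrix.present.loc[locus, carriers]
                carrying = [i for i in carriers if present[i]]
                ratios = [matrix.depth.loc[locus, i] / scale[i] for i in carrying]
                rows.append(
                    {
                        "catalog_id": locus,
                        "sex": sex,
                        "n_carriers": len(carrying),
                        "mean_normalized_depth": float(np.mean(ratios)) if ratios else np.nan,
                    }
                )
    return pd.DataFrame(rows, columns=["catalog_id", "sex", "n_carriers", "mean_normalized_depth"])


def depth_filter(
    candidates: CandidateSet,
    matrix: PresenceMatrix,
    ratio_window: tuple[float, float] = (0.3, 0.7),
    min_autosomal_loci: int = 50,
) -> CandidateSet:
    """Stage C: retain candidates whose mean carrier depth ratio is ~half.

    A hemizygous locus should sit near 0.5 of the carrier's autosomal depth
    scale; candidates behaving autosomally (ratio ~1) are presence/absence
    artifacts of coverage and are dropped.
    """
    if candidates.stage != "zygosity":
        raise ValueError("depth_filter expects a zygosity-stage candidate set")
    low, high = ratio_window
    ratios = carrier_depth_ratios(candidates, matrix, min_autosomal_loci)
    if ratios.empty:
        return CandidateSet("depth", (), ())
    ok = ratios[(ratios["mean_normalized_depth"] >= low) & (ratios["mean_normalized_depth"] <= high)]
    f = tuple(ok[ok["sex"] == "female"]["catalog_id"])
    m = tuple(ok[ok["sex"] == "male"]["catalog_id"])
    return CandidateSet("depth", f, m)


def run_cascade(
    matrix: PresenceMatrix,
    min_presence_frac: float = 1.0,
    ratio_window: tuple[float, float] = (0.3, 0.7),
    min_autosomal_loci: int = 50,
) -> dict[str, CandidateSet]:
    """Run presence -> zygosity -> depth and return all three stages."""
    presence = presence_absence_scan(matrix, min_presence_frac)
    zygosity = zygosity_filter(presence, matrix)
    depth = depth_filter(zygosity, matrix, ratio_window, min_autosomal_loci)
    return {"presence": presence, "zygosity": zygosity, "depth": depth}


# ---------------------------------------------------------------------------
# Saturation analysis
# ---------------------------------------------------------------------------

def saturation_curve(
    matrix: PresenceMatrix,
    subset_sizes: Sequence[int],
    replicates: int = 20,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Stage-A candidate counts on growing subsets of individuals.

    For each replicate a random permutation of each sex is drawn once and
    the first n individuals of each are used at every subset size, so the
    subsets are *nested* within a replicate and candidate counts are
    non-increasing in n by the set-intersection property.  Returns one row
    per (replicate, n) with female- and male-specific counts.
    """
    rng = rng or np.random.default_rng()
    females = matrix.of_sex("female")
    males = matrix.of_sex("male")
    sizes = sorted(subset_sizes)
    if sizes and (sizes[-1] > len(females) or sizes[-1] > len(males)):
        raise ValueError("subset sizes exceed the available individuals per sex")
    rows = []
    for rep in range(replicates):
        f_order = list(rng.permutation(females))
        m_order = list(rng.permutation(males))
        for n in sizes:
            sub = matrix.subset(f_order[:n] + m_order[:n])
            cands = presence_absence_scan(sub)
            nf, nm = cands.counts()
            rows.append({"replicate": rep, "n_per_sex": n, "female_specific": nf, "male_specific": nm})
    return pd.DataFrame(rows)


def saturation_summary(curve: pd.DataFrame) -> pd.DataFrame:
    """Mean candidate counts per subset size (the Fig. S3-style table)."""
    return (
        curve.groupby("n_per_sex")[["female_specific", "male_specific"]]
        .mean()
        .rename(columns=lambda c: f"mean_{c}")
        .reset_index()
    )


def plot_saturation(curve: pd.DataFrame, path: str | Path) -> None:
    """Log-scale saturation plot (mean candidate counts vs individuals/sex)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = saturation_summary(curve)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(summary["n_per_sex"], summary["mean_female_specific"], "o-", label="female-specific")
    ax.plot(summary["n_per_sex"], summary["mean_male_specific"], "s-", label="male-specific")
    ax.set_xlabel("individuals per sex")
    ax.set_ylabel("mean sex-specific candidate loci")
    ax.set_yscale("symlog", linthresh=1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def candidates_to_frame(stages: Mapping[str, CandidateSet], matrix: PresenceMatrix) -> pd.DataFrame:
    """Tidy per-stage candidate table for export."""
    rows = []
    for stage in ("presence", "zygosity", "depth"):
        cands = stages[stage]
        for sex, loci in (("female", cands.female_specific), ("male", cands.male_specific)):
            carriers = matrix.of_sex(sex)
            for locus in loci:
                haps = matrix.haplotype_count.loc[locus, carriers]
                rows.append(
                    {
                        "stage": stage,
                        "catalog_id": locus,
                        "sex": sex,
                        "carrier_haplotype_counts": ",".join(str(int(h)) for h in haps),
                        "mean_depth": float(matrix.depth.loc[locus, carriers].mean()),
                    }
                )
    return pd.DataFrame(rows, columns=["stage", "catalog_id", "sex", "carrier_haplotype_counts", "mean_depth"])
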
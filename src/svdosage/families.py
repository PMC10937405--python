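"""Pan-genome classification of syntenic gene families.

A family is *present* in a genome when its copy count there is >= 1.
With n panel genomes: core = present in all n; softcore = present in at
least ceil(0.9*n) but not all (25-26 for n = 27); private = present in
exactly one; dispensable = everything in between.  Loss analyses use the
literal strict ">50% retained" eligibility rule, and a morphotype claims
a family's loss only when it accounts for strictly more than 70% of the
losing genomes.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger("svdosage")

PAN_CLASSES = ("core", "softcore", "dispensable", "private")

LOSS_RETENTION_MIN_FRAC = 0.50  # strict: retained in > 50% of genomes
MORPHOTYPE_LOSS_MIN_FRAC = 0.70  # strict: > 70% of losers in one morphotype


def softcore_threshold(n_genomes: int) -> int:
    """Minimum presence count for the softcore class (25 for n = 27)."""
    return math.ceil(0.90 * n_genomes)


def classify_families(
    fm: pd.DataFrame, n_genomes: Optional[int] = None
) -> pd.Series:
    """Assign each family to core/softcore/dispensable/private.

    ``fm`` is a family x genome copy-count matrix.  Families present in no
    genome are invalid input.
    """
    if n_genomes is None:
        n_genomes = fm.shape[1]
    elif n_genomes != fm.shape[1]:
        raise ValueError(
            f"n_genomes={n_genomes} but matrix has {fm.shape[1]} genome columns"
        )
    presence = (fm >= 1).sum(axis=1)
    if (presence == 0).any():
        bad = presence.index[presence == 0].tolist()
        raise ValueError(f"families present in zero genomes: {bad[:5]}")
    soft_lo = softcore_threshold(n_genomes)
    classes = pd.Series("dispensable", index=fm.index, name="pan_class")
    classes[presence == n_genomes] = "core"
    classes[(presence >= soft_lo) & (presence < n_genomes)] = "softcore"
    classes[presence == 1] = "private"
    return classes


def genome_composition(fm: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """Per-genome counts and fractions of each pan-class among the
    families present in that genome (fractions sum to 1 per genome)."""
    rows = []
    for genome in fm.columns:
        present = fm.index[fm[genome] >= 1]
        cls = classes.loc[present]
        counts = cls.value_counts().reindex(PAN_CLASSES, fill_value=0)
        total = counts.sum()
        for c in PAN_CLASSES:
            rows.append(
                (genome, c, int(counts[c]), counts[c] / total if total else np.nan)
            )
    return pd.DataFrame(rows, columns=["genome", "pan_class", "count", "fraction"])


def morphotype_specific_loss(
    fm: pd.DataFrame, genome_morphotypes: Mapping[str, str]
) -> pd.DataFrame:
    """Flag families whose losses concentrate in one morphotype.

    Eligible families are lost in >=1 genome yet retained in strictly more
    than half of the panel.  A family is flagged for morphotype M when
    strictly more than 70% of its losing genomes belong to M.
    """
    missing = [g for g in fm.columns if g not in genome_morphotypes]
    if missing:
        raise ValueError(f"genomes without morphotype label: {missing[:5]}")
    n = fm.shape[1]
    morph = pd.Series({g: genome_morphotypes[g] for g in fm.columns})
    rows = []
    for fam, counts in fm.iterrows():
        lost = counts.index[counts == 0]
        retained = n - len(lost)
        eligible = len(lost) >= 1 and retained > LOSS_RETENTION_MIN_FRAC * n
        flag = None
        if eligible:
            loser_morphs = morph.loc[lost].value_counts()
            top = loser_morphs.idxmax()
            if loser_morphs[top] > MORPHOTYPE_LOSS_MIN_FRAC * len(lost):
                flag = top
        rows.append((fam, eligible, len(lost), flag))
    return pd.DataFrame(
        rows, columns=["family_id", "eligible", "n_lost", "morphotype"]
    ).set_index("family_id")


def homoeolog_retention(
    fm: pd.DataFrame,
    triplets: Mapping[str, Mapping[str, str]],
    reference_genome: str,
) -> pd.DataFrame:
    """Per-triplet homoeolog copy-retention patterns across genomes.

    ``triplets`` maps triplet id -> {subgenome label -> family id}.  A
    triplet descends from an ancestral three-copy gene when all three of
    its families are present in the reference genome; it enters the
    analysis when additionally all three copies are retained in strictly
    more than half of the genomes and at least one genome lost a copy.
    Output rows give, per eligible triplet and genome, the retained-copy
    pattern (e.g. ``LF+MF1``).
    """
    if reference_genome not in fm.columns:
        raise ValueError(f"reference genome {reference_genome!r} not in matrix")
    n = fm.shape[1]
    rows = []
    for trip_id, members in triplets.items():
        fams = dict(members)
        if len(fams) != 3:
            continue  # not an ancestral three-copy gene
        unknown = [f for f in fams.values() if f not in fm.index]
        if unknown:
            logger.warning("triplet %s skipped: families %s absent", trip_id, unknown)
            continue
        sub = fm.loc[list(fams.values())]
        if (sub[reference_genome] < 1).any():
            continue  # not three-copy in the reference
        present = sub >= 1
        all_three = present.all(axis=0)
        if not (all_three.sum() > LOSS_RETENTION_MIN_FRAC * n):
            continue
        if all_three.all():
            continue  # no loss anywhere: uninformative
        subg_by_fam = {fam: sg for sg, fam in fams.items()}
        for genome in fm.columns:
            kept = sorted(
                subg_by_fam[fam] for fam in fams.values() if fm.at[fam, genome] >= 1
            )
            rows.append((trip_id, genome, "+".join(kept) if kept else "none", len(kept)))
    return pd.DataFrame(rows, columns=["triplet_id", "genome", "pattern", "n_copies"])
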
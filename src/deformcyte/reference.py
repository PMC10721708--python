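"""Reference-study constants for the fetal-vs-adult RBC cytometry design.

The pipeline is modelled on a deformability-cytometry study of 164 blood
donors (fetal cord-blood and adult donors) imaged at 500 fps in a 5 µm
microfluidic constriction, with the 27 226 detected cells partitioned into
five donor-disjoint splits (four cross-validation folds plus one test set).
This module records that cohort layout and the summary statistics of its
donor-effect analysis so they can be used as inputs: split balancing is
benchmarked against the published allocation, and the closed-form statistics
in :mod:`deformcyte.donor_stats` are exercised on the published sums of
squares.

Nothing here is computed; these are the design constants the rest of the
package reproduces or consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Total number of cells across all five splits.
TOTAL_CELLS = 27226

#: Total number of donors across all five splits.
TOTAL_DONORS = 164


@dataclass(frozen=True)
class SplitComposition:
    """Donor and cell counts of one donor-disjoint split, by class."""

    name: str
    donors_fetal: int
    donors_adult: int
    cells_fetal: int
    cells_adult: int

    @property
    def donors(self) -> int:
        return self.donors_fetal + self.donors_adult

    @property
    def cells(self) -> int:
        return self.cells_fetal + self.cells_adult


#: The five donor-disjoint splits: four training/validation folds and the
#: held-out test set, each holding roughly 20% of all cells.
REFERENCE_SPLITS: tuple[SplitComposition, ...] = (
    SplitComposition("set1", donors_fetal=12, donors_adult=20,
                     cells_fetal=1976, cells_adult=3264),
    SplitComposition("set2", donors_fetal=13, donors_adult=21,
                     cells_fetal=2233, cells_adult=3380),
    SplitComposition("set3", donors_fetal=17, donors_adult=15,
                     cells_fetal=2707, cells_adult=2543),
    SplitComposition("set4", donors_fetal=10, donors_adult=24,
                     cells_fetal=1553, cells_adult=4032),
    SplitComposition("test", donors_fetal=13, donors_adult=19,
                     cells_fetal=2134, cells_adult=3404),
)

#: Fetal red blood cells have a mean volume 21% larger than adult ones;
#: under isotropic scaling the projected-area consequence is 1.21**(2/3).
FETAL_VOLUME_RATIO = 1.21
FETAL_AREA_RATIO = FETAL_VOLUME_RATIO ** (2.0 / 3.0)

# ---------------------------------------------------------------------------
# Donor-effect analysis of the reference study: a balanced 32-donor x 4-fold
# accuracy grid, analysed with the mixed model
#   A_{d,f} = mu + alpha(D_d) + a(F_f) + eps,  a ~ N(0, sigma_A^2).
# The quantities below are its published summaries; the closed forms in
# donor_stats reproduce the derived ones (p-values, F statistics) exactly.
# ---------------------------------------------------------------------------

#: Likelihood-ratio statistic for the fold random-effect variance
#: (boundary test of sigma_A^2 = 0 on a 32x4 grid).
REFERENCE_LRT = 0.5662952

#: One-way donor ANOVA on the same grid (folds as replicates).
REFERENCE_DONOR_ANOVA = {
    "ss_donor": 0.03599925,
    "df_donor": 31,
    "ms_donor": 0.001161266,
    "ss_resid": 0.15538328,
    "df_resid": 96,
    "ms_resid": 0.001618576,
}

#: Between-class ANOVA on the 32 donor-mean accuracies (fetal vs adult).
REFERENCE_CLASS_ANOVA = {
    "ss_class": 0.0000309,
    "df_class": 1,
    "ms_class": 0.00003088,
    "ss_resid": 0.0089689,
    "df_resid": 30,
    "ms_resid": 0.00029896,
}


def reference_donor_specs(cells_per_split=None, seed: int = 0):
    """Donor specifications reproducing the reference cohort layout.

    Each split's per-class cell total is distributed as evenly as possible
    across that split's donors of the class, so the manifest built from the
    returned specs reproduces the published per-split and total cell counts
    exactly.

    Returns a list of :class:`deformcyte.synthetic.DonorSpec`.
    """
    from .synthetic import DonorSpec

    donors = []
    for si, split in enumerate(REFERENCE_SPLITS):
        for label, n_donors, n_cells in (
            ("fetal", split.donors_fetal, split.cells_fetal),
            ("adult", split.donors_adult, split.cells_adult),
        ):
            base, extra = divmod(n_cells, n_donors)
            for j in range(n_donors):
                donors.append(
                    DonorSpec(
                        donor_id=f"{split.name}-{label[0].upper()}{j + 1:02d}",
                        class_label=label,
                        n_cells=base + (1 if j < extra else 0),
                        seed=seed + 1000 * si + len(donors),
                    )
                )
    return donors
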
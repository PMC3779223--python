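"""Canonical simulation experiments over synthetic superfamilies.

These are the study conditions used throughout the test suite and the
reproduction script: 10-member superfamilies built from a 120-residue
common core with 0.3 Å isotropic noise, with (or without) the canonical
two-hinge perturbation planted on member 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import deviation as dv
from . import synthetic_data as sd
from .superposition import multiple_superpose

N_MEMBERS = 10
CORE_LENGTH = 120
NOISE_SD = 0.3


def two_hinge_spec(seed: int, n_members: int = N_MEMBERS,
                   core_length: int = CORE_LENGTH,
                   noise_sd: float = NOISE_SD) -> sd.SyntheticSpec:
    """Spec with the canonical two-hinge perturbation on member 0."""
    return sd.SyntheticSpec(
        n_members=n_members, core_length=core_length, noise_sd=noise_sd,
        outlier_plan=((0, sd.plant_two_hinge_outlier(core_length)),),
        seed=seed)


@dataclass
class PlantedOutlierResult:
    """Per-seed statistics of the planted member (member 0)."""

    seeds: tuple[int, ...]
    mean_rmsd: np.ndarray  # member 0's mean one-against-all RMSD, Å
    tm_median: np.ndarray  # median TM-score of member 0 vs the others
    tm_max: np.ndarray  # worst case: max TM-score of member 0 vs any other

    def rmsd_exceeds(self, cut: float = dv.DEFAULT_RMSD_CUT) -> float:
        """Fraction of seeds with mean RMSD above *cut*."""
        return float(np.mean(self.mean_rmsd > cut))

    def tm_below(self, cut: float = dv.DEFAULT_TM_CUT,
                 per_pair: bool = False) -> float:
        """Fraction of seeds with (median, or every) TM-score below *cut*."""
        vals = self.tm_max if per_pair else self.tm_median
        return float(np.mean(vals < cut))


def run_planted_outlier(seeds: Iterable[int],
                        tm_params: dv.TMScoreParams | None = None
                        ) -> PlantedOutlierResult:
    """Generate, superpose and score the planted member for each seed."""
    tm_params = tm_params or dv.TMScoreParams()
    seeds = tuple(int(s) for s in seeds)
    mean_rmsds, tm_medians, tm_maxes = [], [], []
    for seed in seeds:
        structures, aln, _, _ = sd.make_superfamily(two_hinge_spec(seed))
        ensemble = multiple_superpose(aln, structures)
        M = dv.rmsd_matrix(aln, structures, ensemble)
        mean_rmsds.append(dv.mean_rmsd(M, 0))
        planted = structures[0]
        tms = [dv.tm_score(aln, planted, other, tm_params)
               for other in structures[1:]]
        tm_medians.append(float(np.median(tms)))
        tm_maxes.append(float(np.max(tms)))
    return PlantedOutlierResult(seeds=seeds,
                                mean_rmsd=np.asarray(mean_rmsds),
                                tm_median=np.asarray(tm_medians),
                                tm_max=np.asarray(tm_maxes))


def run_null(seeds: Iterable[int], noise_sd: float = NOISE_SD,
             rmsd_cut: float = dv.DEFAULT_RMSD_CUT,
             tm_cut: float = dv.DEFAULT_TM_CUT) -> np.ndarray:
    """Outlier counts for unperturbed ensembles (should be all zero)."""
    counts = []
    for seed in seeds:
        spec = sd.SyntheticSpec(n_members=N_MEMBERS,
                                core_length=CORE_LENGTH,
                                noise_sd=noise_sd, seed=int(seed))
        structures, aln, _, _ = sd.make_superfamily(spec)
        ensemble = multiple_superpose(aln, structures)
        report = dv.classify_outliers(aln, structures, ensemble,
                                      rmsd_cut=rmsd_cut, tm_cut=tm_cut)
        counts.append(len(report.outliers))
    return np.asarray(counts)
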
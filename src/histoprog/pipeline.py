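"""End-to-end study orchestration on synthetic or user-supplied tables.

``simulate_study`` draws one internal training cohort plus two
domain-shifted external cohorts (mirroring a multi-institution design);
``run_study`` executes the full protocol — intermediate reasoning, the five
final model configurations, internal 3-fold cross-validation and external
validation — and collects AUROC and Brier tables per cohort and
configuration.  ``featurize_slides`` is the image path: tile, flag tissue,
embed, assign against a codebook and tally compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .evaluation import EvaluationReport, external_protocol, kfold_protocol
from .features import EmbeddingBackend, Codebook, assign, compose
from .prognosis import MODEL_CONFIGS
from .synthetic import (CohortConfig, DEFAULT_EXTERNAL_SHIFT,
                        counts_to_fractions, generate_cohort)
from .tiling import flag_tissue, tile

__all__ = ["simulate_study", "run_study", "featurize_slides", "StudyData"]


@dataclass
class StudyData:
    """One simulated multi-institution study: training + external cohorts."""

    train: pd.DataFrame
    train_compositions: pd.DataFrame
    externals: dict[str, tuple[pd.DataFrame, pd.DataFrame]]


def simulate_study(seed: int = 0, n_train: int = 170,
                   n_external: tuple[int, ...] = (71, 39),
                   n_clusters: int = 100,
                   shift=DEFAULT_EXTERNAL_SHIFT) -> StudyData:
    """Draw one internal and len(n_external) shifted external cohorts.

    Cohort sizes default to 170 training and (71, 39) external patients.
    The external cohorts share the internal outcome mechanism but have
    shifted marginal composition statistics.
    """
    base = CohortConfig(n_patients=n_train, cohort="internal",
                        n_clusters=n_clusters,
                        seed=child_seed(seed, "study", "internal"))
    train, train_counts = generate_cohort(base)
    externals = {}
    for i, n_ext in enumerate(n_external):
        label = f"external-{chr(ord('A') + i)}"
        cfg = replace(base, n_patients=n_ext, cohort=label, shift=shift,
                      seed=child_seed(seed, "study", label))
        ext, ext_counts = generate_cohort(cfg)
        externals[label] = (ext, counts_to_fractions(ext_counts))
    return StudyData(train=train,
                     train_compositions=counts_to_fractions(train_counts),
                     externals=externals)


def run_study(data: StudyData, configs=MODEL_CONFIGS, seed: int = 0,
              n_boot: int = 10_000, cv_folds: int = 3,
              internal: bool = True
              ) -> tuple[pd.DataFrame, pd.DataFrame,
                         dict[str, dict[str, EvaluationReport]]]:
    """Run internal CV + external validation for the chosen configurations.

    Returns ``(auroc_table, brier_table, reports)``: the first two are
    cohort x configuration tables (AUROC formatted with its bootstrap CI;
    Brier as numbers), ``reports`` holds the full per-cohort
    :class:`EvaluationReport` objects.
    """
    reports: dict[str, dict[str, EvaluationReport]] = {}
    if internal:
        reports["internal"] = kfold_protocol(
            data.train, data.train_compositions, configs=configs,
            k=cv_folds, seed=seed, n_boot=n_boot, cohort_label="internal")
    reports.update(external_protocol(
        data.train, data.train_compositions, data.externals,
        configs=configs, seed=seed, n_boot=n_boot))

    auroc_rows, brier_rows = [], []
    for cohort_label, per_cfg in reports.items():
        arow: dict = {"cohort": cohort_label}
        brow: dict = {"cohort": cohort_label}
        for cfg_name, rep in per_cfg.items():
            arow[cfg_name] = (f"{rep.auroc:.3f} "
                              f"[95% CI {rep.ci_low:.3f}-{rep.ci_high:.3f}]")
            brow[cfg_name] = round(rep.brier, 3)
        auroc_rows.append(arow)
        brier_rows.append(brow)
    return (pd.DataFrame(auroc_rows).set_index("cohort"),
            pd.DataFrame(brier_rows).set_index("cohort"), reports)


def featurize_slides(slides: dict[str, np.ndarray], backend: EmbeddingBackend,
                     codebook: Codebook, patch_size: int, stride: int | None = None,
                     s_min: float = 0.08, v_max: float = 0.95,
                     f_min: float = 0.5) -> pd.DataFrame:
    """Tile, flag, embed and compose each slide into a composition matrix.

    ``slides`` maps sample id to an RGB image.  Returns a (samples x k)
    fraction matrix with rows summing to 1.
    """
    rows = {}
    for sample_id, image in slides.items():
        ps = flag_tissue(tile(image, patch_size, stride, slide_id=sample_id),
                         s_min=s_min, v_max=v_max, f_min=f_min)
        tissue_idx = np.flatnonzero(ps.tissue)
        if tissue_idx.size == 0:
            raise ValueError(f"slide {sample_id!r} has no tissue patches")
        emb = backend.embed([ps.patch(i) for i in tissue_idx])
        labels = assign(codebook, emb)
        rows[sample_id] = compose(labels, codebook.k,
                                  sample_id=sample_id).fractions
    from .synthetic import cluster_columns
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=cluster_columns(codebook.k))
    out.index.name = "patient_id"
    return out
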
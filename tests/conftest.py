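"""Shared fixtures: one seed-0 default synthetic study and its pipeline run.

Session scope keeps the expensive objects (the five-phenotype MI network
family) computed once for the whole suite.
"""

from __future__ import annotations

import pytest

from mirgenet.minet import MIEstimatorConfig
from mirgenet.preprocess import filter_features
from mirgenet.stagenet import build_stage_series
from mirgenet.synthetic_data import DEFAULT_STUDY_K, default_study, generate

HOUSE_SEED = 0


@pytest.fixture(scope="session")
def study():
    """(gene_mat, mir_mat, samples, annotation, truth) at the house seed."""
    return generate(default_study(HOUSE_SEED))


@pytest.fixture(scope="session")
def filtered(study):
    gene_mat, mir_mat, _, annot, _ = study
    genes_f, gene_report = filter_features(gene_mat, annot)
    mirs_f, mir_report = filter_features(mir_mat, None)
    return genes_f, mirs_f, gene_report, mir_report


@pytest.fixture(scope="session")
def series(study, filtered):
    """Full stage series (5 top-K + 4 canonical networks) at the house seed."""
    _, _, samples, _, _ = study
    genes_f, mirs_f, _, _ = filtered
    return build_stage_series(
        genes_f, mirs_f, samples, MIEstimatorConfig(), k=DEFAULT_STUDY_K
    )
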
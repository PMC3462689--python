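"""Shared fixtures: seeded synthetic libraries and their pipeline products."""

from __future__ import annotations

import pytest

from smallrna_forge.annotate import ReferenceSet, build_index, classify_all
from smallrna_forge.preprocess import run_cascade
from smallrna_forge.simulate import SimConfig, generate_library


@pytest.fixture(scope="session")
def small_lib():
    """A 3,000-read library: fast enough for per-module checks."""
    return generate_library(
        SimConfig(seed=5, n_reads=3000, spike_count_range=(20, 200))
    )


@pytest.fixture(scope="session")
def study_lib():
    """The 10,000-read default-condition library used for truth recovery."""
    return generate_library(SimConfig(seed=11))


@pytest.fixture(scope="session")
def study_tags_stats(study_lib):
    return run_cascade(study_lib.reads)


def reference_sets(lib):
    return [
        ReferenceSet("rRNA", lib.refs["rRNA"], "rRNA"),
        ReferenceSet("tRNA", lib.refs["tRNA"], "tRNA"),
        ReferenceSet("snRNA", lib.refs["snRNA"], "snRNA"),
        ReferenceSet("snoRNA", lib.refs["snoRNA"], "snoRNA"),
        ReferenceSet("repeat", lib.refs["repeat"], "repeat"),
        ReferenceSet("known_miRNA", lib.refs["mature_mirna"], "known_miRNA_mature"),
        ReferenceSet("exon", lib.refs["transcripts"], "exon"),
    ]


@pytest.fixture(scope="session")
def study_annotation(study_lib, study_tags_stats):
    tags, stats = study_tags_stats
    index = build_index(reference_sets(study_lib))
    return classify_all(tags, index)
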
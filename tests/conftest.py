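"""Shared fixtures: one synthetic dataset and one pipeline run per session."""

from __future__ import annotations

import hashlib
import os
import time

import pytest

import lncnet as ln
from lncnet.pipeline import PipelineConfig, run_pipeline

DATASET_SEED = 5


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Generator-default synthetic dataset (seed 5) written to disk."""
    outdir = tmp_path_factory.mktemp("sim")
    truth = ln.generate_dataset(str(outdir), seed=DATASET_SEED)
    return {"dir": str(outdir), "truth": truth}


@pytest.fixture(scope="session")
def annotation(dataset):
    with open(os.path.join(dataset["dir"], "annotation.gtf")) as fh:
        return ln.parse_gtf(fh.read())


def _sha_tree(root: str) -> dict[str, str]:
    out = {}
    for base, _dirs, files in os.walk(root):
        for name in files:
            path = os.path.join(base, name)
            with open(path, "rb") as fh:
                out[os.path.relpath(path, root)] = hashlib.sha256(fh.read()).hexdigest()
    return out


@pytest.fixture(scope="session")
def pipeline_run(dataset, tmp_path_factory):
    """The full pipeline run twice on the session dataset, with file hashes."""
    outdir = tmp_path_factory.mktemp("run")
    config = PipelineConfig(
        counts=os.path.join(dataset["dir"], "counts.tsv"),
        design=os.path.join(dataset["dir"], "design.tsv"),
        gtf=os.path.join(dataset["dir"], "annotation.gtf"),
        gmt=os.path.join(dataset["dir"], "genesets.gmt"),
        outdir=str(outdir),
        seed=DATASET_SEED,
    )
    start = time.monotonic()
    run_pipeline(config)
    elapsed = time.monotonic() - start
    hashes_first = _sha_tree(str(outdir))
    run_pipeline(config)
    hashes_second = _sha_tree(str(outdir))
    return {
        "dir": str(outdir),
        "config": config,
        "elapsed": elapsed,
        "hashes": (hashes_first, hashes_second),
        "truth": dataset["truth"],
    }
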
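"""Shared fixtures: a small synthetic study and record factories."""

from __future__ import annotations

import pytest

from famprior.synthetic import SynthConfig, generate_study
from famprior.types import Category, Genotype, VariantRecord


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A 6-family synthetic study with default planting, generated once."""
    outdir = tmp_path_factory.mktemp("synth_small")
    cfg = SynthConfig(seed=7, n_families=6)
    manifest = generate_study(cfg, outdir)
    # manifest paths are relative to the study directory; resolve for tests
    manifest["files"] = {k: str(outdir / v) for k, v in manifest["files"].items()}
    return cfg, manifest, outdir


@pytest.fixture()
def make_variant():
    def _make(
        chrom="1",
        pos=100,
        ref="A",
        alt="T",
        category=Category.UTR5,
        gene="GENE1",
        genotypes=None,
        **kwargs,
    ):
        return VariantRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            category=category,
            gene=gene,
            genotypes=genotypes or {},
            **kwargs,
        )

    return _make


@pytest.fixture()
def gt():
    def _gt(alt_count, depth=30):
        if alt_count is None:
            return Genotype(None, depth, missing=True)
        return Genotype(alt_count, depth)

    return _gt
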
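"""Canonical in-repo test data: the five-patient 22q13 validation panel.

``validation_deletions`` returns the five terminal deletions with printed hg19
breakpoints; ``candidate_genes`` the nine blood-expressed candidate genes with
printed coordinates.  Both are shipped as TSV under ``tadpose/data`` and read
through the ordinary :mod:`tadpose.genome_model` readers, so the fixtures also
exercise the I/O path.
"""

from __future__ import annotations

from importlib import resources

from .genome_model import Deletion, GeneAnnotation, read_deletions, read_genes

__all__ = ["validation_deletions", "candidate_genes", "fixture_path"]


def fixture_path(name: str):
    """Filesystem path of a packaged data file (context-manager-free; the
    package is installed from source, so files are real paths)."""
    return resources.files("tadpose.data").joinpath(name)


def validation_deletions() -> list[Deletion]:
    """The five-patient validation panel (PMS 1-5), largest deletion first."""
    return read_deletions(fixture_path("validation_deletions.tsv"))


def candidate_genes() -> list[GeneAnnotation]:
    """The nine blood-expressed candidate genes, ordered by coordinate."""
    return read_genes(fixture_path("candidate_genes.tsv"))
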
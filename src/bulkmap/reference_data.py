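"""Published reference interval tables bundled with the package.

The two TSVs under ``data/`` list the genomic intervals reported for seed
glucosinolate content (GSL, 30 intervals) and seed protein/oil content
(SPC, 15 intervals) in the *Brassica napus* Lorenz x Janetzkis
Schlesischer F2 mapping experiment this pipeline re-implements.  They
serve as fixtures for the report format: the size column must equal
end - start, and the per-chromosome tallies are known.
"""

from __future__ import annotations

from importlib import resources

from .intervals import GenomicInterval

_FILES = {"GSL": "gsl_intervals.tsv", "SPC": "spc_intervals.tsv"}


def reference_interval_path(trait: str):
    """Filesystem path of the bundled interval table for ``trait``."""
    try:
        fname = _FILES[trait.upper()]
    except KeyError:
        raise ValueError(f"unknown trait {trait!r}; use one of {sorted(_FILES)}")
    return resources.files("bulkmap.data").joinpath(fname)


def load_reference_intervals(trait: str) -> list[GenomicInterval]:
    """Load the bundled GSL or SPC interval table as GenomicInterval records."""
    from .io_formats import read_interval_table

    with resources.as_file(reference_interval_path(trait)) as path:
        return read_interval_table(path)
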
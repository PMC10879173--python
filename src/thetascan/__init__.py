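"""thetascan: discovery and validation toolkit for tRNA-processing
HDV-like ribozymes.

Subpackages/modules:

* :mod:`thetascan.motif_engine` — descriptor parsing and structural motif search
* :mod:`thetascan.trna_annotate` — tRNA association and genomic context
* :mod:`thetascan.recoding` — coding density and genetic-code assignment
* :mod:`thetascan.kinetics` — self-scission kinetics models and fits
* :mod:`thetascan.synthetic_data` — ground-truth synthetic genomes and reads
* :mod:`thetascan.cli` — command-line pipeline
"""

__version__ = "0.1.0"

from importlib import resources


def data_path(name: str):
    """Path to a shipped data file (e.g. ``minimal_drz.desc``)."""
    return resources.files(__name__) / "data" / name


def load_builtin_descriptor(name: str):
    """Load a shipped descriptor by file name ('minimal_drz' or 'theta_final')."""
    from .motif_engine import parse_descriptor

    if not name.endswith(".desc"):
        name += ".desc"
    text = data_path(name).read_text(encoding="utf-8")
    return parse_descriptor(text, name=name.removesuffix(".desc"))
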
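"""Bundled fixtures: the reduced liver network (JSON) and the two media
tables (TSV), byte-for-byte what ``nashflux make-fixtures`` writes.

These are convenience copies of programmatically generated objects; the
builders in :mod:`nashflux.liver` and :mod:`nashflux.media` remain the
source of truth and a test keeps the two in sync.
"""

from importlib import resources

from ..media import Medium, load_medium_tsv
from ..network import MetabolicNetwork, load_network

__all__ = ["bundled_network", "bundled_medium"]


def _path(name: str):
    return resources.files(__name__) / name


def bundled_network() -> MetabolicNetwork:
    """The shipped reduced liver network."""
    return load_network(_path("reduced_liver_network.json"))


def bundled_medium(name: str) -> Medium:
    """A shipped medium table: ``"uw_solution"`` or ``"williams_medium_e"``."""
    return load_medium_tsv(_path(f"{name}.tsv"))
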
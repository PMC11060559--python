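"""Small bundled reference tables."""

from importlib import resources

from ..io import LibraryMeta, read_library_metadata

__all__ = ["load_study_metadata"]


def load_study_metadata(species: str | None = None) -> list[LibraryMeta]:
    """Metadata of the 22 pooled-mosquito libraries of the emulated study.

    One row per sequencing library: mosquito species, collection site,
    habitat type, sampling year and the number of pooled females.
    Optionally filter to one mosquito species (substring match on the
    genus or full name, e.g. ``"Culex"`` or ``"Aedes vexans"``).
    """
    path = resources.files(__package__) / "study_library_metadata.tsv"
    with resources.as_file(path) as p:
        metas = read_library_metadata(p)
    if species is not None:
        metas = [m for m in metas if species.lower() in m.species.lower()]
    return metas
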
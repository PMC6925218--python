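"""Built-in editable resources (cell-cycle phase gene lists, marker config)."""

from importlib import resources as _res

import yaml


def _load_yaml(name: str):
    with _res.files(__package__).joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def load_cell_cycle_genes() -> dict[str, list[str]]:
    """Phase name -> gene list for cell-cycle scoring."""
    return _load_yaml("cell_cycle_genes.yaml")


def load_marker_config() -> dict:
    """Default marker thresholds and cell-type map for cluster labeling."""
    return _load_yaml("markers.yaml")
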
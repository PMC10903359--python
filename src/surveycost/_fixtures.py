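"""Access to the small CSV fixtures packaged with the library."""

from importlib import resources
from pathlib import Path


def packaged_data_path(name: str) -> Path:
    """Filesystem path of a packaged data file (editable and wheel installs)."""
    return Path(resources.files("surveycost").joinpath("data", name))
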
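import sys
from pathlib import Path

# make sibling test modules importable (the equation oracle lives in
# test_deconvolve and is shared with the end-to-end suite)
sys.path.insert(0, str(Path(__file__).parent))
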
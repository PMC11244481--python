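import numpy as np

from ginfunnel.data_io import ExpressionMatrix


def make_expr(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes=genes, samples=samples, values=values)
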
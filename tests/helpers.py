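import numpy as np
import pandas as pd

from budchill.thermal import HourlyTemperatureSeries


def make_series(temps, start="2018-01-01") -> HourlyTemperatureSeries:
    temps = np.asarray(temps, dtype=float)
    ts = pd.date_range(start, periods=len(temps), freq="h")
    return HourlyTemperatureSeries(timestamps=ts, temp_c=temps)


def constant_series(value: float, hours: int, start="2018-01-01") -> HourlyTemperatureSeries:
    return make_series(np.full(hours, value), start=start)


def profile_matrix(values, genes=None, dates=None, cultivars=("A", "B")):
    """Wrap a (genes x cells) array as an ExpressionProfileMatrix."""
    from budchill.expression import ExpressionProfileMatrix

    values = np.asarray(values, dtype=float)
    n_genes, n_cols = values.shape
    if dates is None:
        dates = pd.date_range("2017-10-01", periods=n_cols // len(cultivars), freq="7D")
    cols = pd.MultiIndex.from_product([dates, list(cultivars)], names=["date", "cultivar"])
    genes = genes or [f"g{i}" for i in range(n_genes)]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=cols)
    return ExpressionProfileMatrix(values=df, counts=df.notna().astype(int))
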
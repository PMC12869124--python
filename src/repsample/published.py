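"""Published counts and cost summaries for the four Korean cancer sample cohorts.

The K-CURE programme released nationally representative sample cohorts for
stomach, breast, colorectal and liver cancer, drawn from the registry-linked
target population of patients diagnosed 2012-2019.  The release publishes,
per cancer type, population and sample counts by age group, sex, region
(3-group recode), SEER summary stage and incidence year, and per-cancer,
per-age-group mean +/- SD of total medical cost in the incidence year (USD,
at 1 USD = 1,300 KRW).

Those printed tables are inputs here, in two roles:

* :func:`repsample.report` arithmetic (sampling fractions, age proportions,
  sex rate ratios) is reproducible from the counts alone;
* the synthetic registry generator uses the count marginals and the cost
  summaries as its default study conditions.
"""

from __future__ import annotations

import io

import pandas as pd

CANCER_TYPES = ["stomach", "breast", "colorectal", "liver"]

AGE_GROUPS = ["0-39", "40-49", "50-59", "60-69", "70-79", "80+"]

SEER_STAGES = ["in situ", "localized", "regional", "distant", "unknown"]

REGIONS_17 = [
    "Seoul", "Busan", "Daegu", "Incheon", "Gwangju", "Daejeon", "Ulsan",
    "Sejong", "Gyeonggi", "Gangwon", "Chungbuk", "Chungnam", "Jeonbuk",
    "Jeonnam", "Gyeongbuk", "Gyeongnam", "Jeju",
]

REGIONS_3 = ["metropolitan", "city", "rural"]

# Long format: one row per (cancer, variable, level); population and sample
# counts as printed.  Missing cells (breast males, liver in situ) omitted.
_COUNTS_CSV = """\
cancer,variable,level,population,sample
stomach,age,0-39,6741,1691
stomach,age,40-49,23547,5214
stomach,age,50-59,55963,11608
stomach,age,60-69,69168,14180
stomach,age,70-79,65297,13358
stomach,age,80+,27387,5900
breast,age,0-39,20264,4178
breast,age,40-49,66292,13321
breast,age,50-59,58075,11714
breast,age,60-69,30659,6329
breast,age,70-79,13830,3024
breast,age,80+,3787,1020
colorectal,age,0-39,7178,1846
colorectal,age,40-49,21895,4837
colorectal,age,50-59,59277,12011
colorectal,age,60-69,70920,14181
colorectal,age,70-79,68748,13729
colorectal,age,80+,33273,6881
liver,age,0-39,2418,724
liver,age,40-49,12192,2942
liver,age,50-59,32870,7026
liver,age,60-69,33084,7042
liver,age,70-79,30083,6439
liver,age,80+,13677,3202
stomach,sex,male,167656,34542
stomach,sex,female,80447,17409
breast,sex,female,192907,39586
colorectal,sex,male,158209,31948
colorectal,sex,female,103082,21537
liver,sex,male,93053,19821
liver,sex,female,31271,7554
stomach,region3,metropolitan,42244,8517
stomach,region3,city,62976,13741
stomach,region3,rural,142883,29693
breast,region3,metropolitan,43230,8611
breast,region3,city,50337,10607
breast,region3,rural,99340,20368
colorectal,region3,metropolitan,51546,10110
colorectal,region3,city,63939,13383
colorectal,region3,rural,145806,29992
liver,region3,metropolitan,20919,4275
liver,region3,city,32258,7367
liver,region3,rural,71147,15733
stomach,stage,in situ,10295,2360
stomach,stage,localized,150082,30346
stomach,stage,regional,48703,10440
stomach,stage,distant,25881,5976
stomach,stage,unknown,13142,2829
breast,stage,in situ,29304,6035
breast,stage,localized,95762,19280
breast,stage,regional,54542,11151
breast,stage,distant,8010,2011
breast,stage,unknown,5289,1109
colorectal,stage,in situ,29193,6201
colorectal,stage,localized,88999,18038
colorectal,stage,regional,93026,18848
colorectal,stage,distant,36349,7764
colorectal,stage,unknown,13724,2634
liver,stage,localized,56618,11949
liver,stage,regional,29937,6672
liver,stage,distant,19255,4561
liver,stage,unknown,18514,4193
stomach,year,2012,31317,6456
stomach,year,2013,31061,6447
stomach,year,2014,30981,6505
stomach,year,2015,30360,6381
stomach,year,2016,31674,6648
stomach,year,2017,31060,6545
stomach,year,2018,30752,6479
stomach,year,2019,30898,6490
breast,year,2012,19263,3950
breast,year,2013,20268,4164
breast,year,2014,21400,4426
breast,year,2015,22502,4638
breast,year,2016,25722,5264
breast,year,2017,26477,5426
breast,year,2018,27852,5703
breast,year,2019,29423,6015
colorectal,year,2012,31604,6393
colorectal,year,2013,31171,6332
colorectal,year,2014,31141,6402
colorectal,year,2015,31628,6495
colorectal,year,2016,33698,6901
colorectal,year,2017,33793,6942
colorectal,year,2018,33727,6913
colorectal,year,2019,34529,7107
liver,year,2012,15715,3400
liver,year,2013,15656,3413
liver,year,2014,15574,3433
liver,year,2015,15623,3451
liver,year,2016,15643,3466
liver,year,2017,15307,3390
liver,year,2018,15515,3430
liver,year,2019,15291,3392
"""

# Total medical cost in the incidence year, USD: per cancer x age group,
# population and sample n / mean / SD as printed.
_COSTS_CSV = """\
cancer,age_group,pop_n,pop_mean,pop_sd,sample_n,sample_mean,sample_sd
stomach,0-39,6741,9398,8320,1691,9604,7955
stomach,40-49,23547,7869,7588,5214,7893,7400
stomach,50-59,55963,8194,8401,11608,8188,7609
stomach,60-69,69168,8562,9849,14180,8588,9604
stomach,70-79,65297,9397,10511,13358,9270,9941
stomach,80+,27387,9623,11504,5900,9672,11711
breast,0-39,20264,10380,7716,4178,10391,7725
breast,40-49,66292,10074,7800,13321,10112,7801
breast,50-59,58075,11297,9291,11714,11341,9381
breast,60-69,30659,11501,9156,6329,11431,8577
breast,70-79,13830,10999,10368,3024,10997,10521
breast,80+,3787,9487,13238,1020,9288,12448
colorectal,0-39,7178,9901,10971,1846,10014,11604
colorectal,40-49,21895,10585,11147,4837,10421,10975
colorectal,50-59,59277,10738,11741,12011,10570,11324
colorectal,60-69,70920,11545,12005,14181,11394,11497
colorectal,70-79,68748,12605,13067,13729,12425,12853
colorectal,80+,33273,12723,14438,6881,12474,13657
liver,0-39,2418,14030,13838,724,13765,13926
liver,40-49,12192,13581,16928,2942,12923,15101
liver,50-59,32870,13558,15303,7026,13316,14218
liver,60-69,33084,13327,15902,7042,13218,18131
liver,70-79,30083,12372,11945,6439,12421,11611
liver,80+,13677,10197,10829,3202,10133,11667
"""


def cohort_counts() -> pd.DataFrame:
    """Published population/sample counts, long format.

    Columns: ``cancer, variable, level, population, sample`` where
    ``variable`` is one of ``age, sex, region3, stage, year``.
    """
    return pd.read_csv(io.StringIO(_COUNTS_CSV), dtype={"level": str})


def cost_summaries() -> pd.DataFrame:
    """Published per cancer x age-group cost summaries (USD)."""
    return pd.read_csv(io.StringIO(_COSTS_CSV))


def counts_for(cancer: str, variable: str) -> pd.Series:
    """Population counts for one cancer and stratification variable,
    indexed by level."""
    df = cohort_counts()
    sub = df[(df.cancer == cancer) & (df.variable == variable)]
    if sub.empty:
        raise KeyError(f"no published counts for {cancer!r}/{variable!r}")
    return sub.set_index("level")["population"]
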
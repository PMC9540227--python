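"""Reference geography for mainland China's 31 provincial units.

Two pieces of static domain data live here: the standard three-region
partition (eastern / central / western, per the 7th Five-Year Plan) and a
queen-contiguity neighbour list for the 31 provincial-level units, with the
customary Hainan-Guangdong bridge so the contiguity graph is connected.
Hong Kong, Macao and Taiwan are not covered.
"""

from __future__ import annotations

EASTERN = [
    "Beijing", "Tianjin", "Hebei", "Liaoning", "Shanghai", "Jiangsu",
    "Zhejiang", "Fujian", "Shandong", "Guangdong", "Hainan",
]
CENTRAL = [
    "Shanxi", "Jilin", "Heilongjiang", "Anhui", "Jiangxi", "Henan",
    "Hubei", "Hunan",
]
WESTERN = [
    "Inner Mongolia", "Guangxi", "Chongqing", "Sichuan", "Guizhou",
    "Yunnan", "Tibet", "Shaanxi", "Gansu", "Qinghai", "Ningxia", "Xinjiang",
]

#: All 31 provinces in region order (eastern, central, western).
PROVINCES = EASTERN + CENTRAL + WESTERN

REGION_LABELS = ["eastern", "central", "western"]

#: province -> region label
REGION_OF = {
    **{p: "eastern" for p in EASTERN},
    **{p: "central" for p in CENTRAL},
    **{p: "western" for p in WESTERN},
}

# Queen contiguity edges (land borders; Hainan linked to Guangdong across
# the Qiongzhou Strait). Each unordered pair listed once.
CONTIGUITY_EDGES = [
    ("Beijing", "Tianjin"), ("Beijing", "Hebei"), ("Tianjin", "Hebei"),
    ("Hebei", "Liaoning"), ("Hebei", "Inner Mongolia"), ("Hebei", "Shanxi"),
    ("Hebei", "Henan"), ("Hebei", "Shandong"),
    ("Shanxi", "Inner Mongolia"), ("Shanxi", "Shaanxi"), ("Shanxi", "Henan"),
    ("Inner Mongolia", "Heilongjiang"), ("Inner Mongolia", "Jilin"),
    ("Inner Mongolia", "Liaoning"), ("Inner Mongolia", "Shaanxi"),
    ("Inner Mongolia", "Ningxia"), ("Inner Mongolia", "Gansu"),
    ("Liaoning", "Jilin"), ("Jilin", "Heilongjiang"),
    ("Shanghai", "Jiangsu"), ("Shanghai", "Zhejiang"),
    ("Jiangsu", "Zhejiang"), ("Jiangsu", "Anhui"), ("Jiangsu", "Shandong"),
    ("Zhejiang", "Anhui"), ("Zhejiang", "Jiangxi"), ("Zhejiang", "Fujian"),
    ("Anhui", "Jiangxi"), ("Anhui", "Hubei"), ("Anhui", "Henan"),
    ("Anhui", "Shandong"),
    ("Fujian", "Jiangxi"), ("Fujian", "Guangdong"),
    ("Jiangxi", "Guangdong"), ("Jiangxi", "Hunan"), ("Jiangxi", "Hubei"),
    ("Shandong", "Henan"),
    ("Henan", "Shaanxi"), ("Henan", "Hubei"),
    ("Hubei", "Shaanxi"), ("Hubei", "Chongqing"), ("Hubei", "Hunan"),
    ("Hunan", "Guangdong"), ("Hunan", "Guangxi"), ("Hunan", "Guizhou"),
    ("Hunan", "Chongqing"),
    ("Guangdong", "Guangxi"), ("Guangdong", "Hainan"),
    ("Guangxi", "Guizhou"), ("Guangxi", "Yunnan"),
    ("Chongqing", "Guizhou"), ("Chongqing", "Sichuan"),
    ("Chongqing", "Shaanxi"),
    ("Sichuan", "Guizhou"), ("Sichuan", "Yunnan"), ("Sichuan", "Tibet"),
    ("Sichuan", "Qinghai"), ("Sichuan", "Gansu"), ("Sichuan", "Shaanxi"),
    ("Guizhou", "Yunnan"),
    ("Yunnan", "Tibet"),
    ("Tibet", "Xinjiang"), ("Tibet", "Qinghai"),
    ("Shaanxi", "Ningxia"), ("Shaanxi", "Gansu"),
    ("Gansu", "Ningxia"), ("Gansu", "Qinghai"), ("Gansu", "Xinjiang"),
    ("Qinghai", "Xinjiang"),
]
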
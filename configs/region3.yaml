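# Sample 17-region -> metropolitan/city/rural recode for released-cohort
# reporting.  The authoritative recode used for the public release is not
# published; stratification always uses the 17 regions, so this mapping
# affects reporting only.  Edit to taste and pass via --region-mapping.
Seoul: metropolitan
Busan: metropolitan
Daegu: metropolitan
Incheon: metropolitan
Gwangju: metropolitan
Daejeon: metropolitan
Ulsan: metropolitan
Sejong: city
Gyeonggi: city
Gangwon: rural
Chungbuk: rural
Chungnam: rural
Jeonbuk: rural
Jeonnam: rural
Gyeongbuk: rural
Gyeongnam: rural
Jeju: rural
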
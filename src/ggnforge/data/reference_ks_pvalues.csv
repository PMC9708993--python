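family,feature,p_value
GLCM,Inverse difference moment,0.984025
GLSZM,Zone percentage,0.934856
GLDM,Small dependence emphasis,0.932657
GLCM,Inverse difference,0.926064
firstorder,Robust mean absolute deviation,0.903346
GLSZM,Small area low grey level emphasis,0.860311
GLRLM,Run percentage,0.827381
GLRLM,High grey level run emphasis,0.729491
GLSZM,Grey level non-uniformity normalised,0.696774
GLRLM,Long run emphasis,0.676057
GLCM,Sum entropy,0.658063
GLRLM,Long run high grey level emphasis,0.652292
GLRLM,Run entropy,0.652292
firstorder,Entropy,0.643479
GLCM,Inverse variance,0.616719
GLRLM,Short run high grey level emphasis,0.582172
GLDM,High grey level emphasis,0.574195
GLCM,Joint energy,0.570327
GLCM,Joint entropy,0.570327
GLRLM,Run length non-uniformity normalised,0.570327
GLRLM,Short run emphasis,0.570327
firstorder,90 percentile,0.541180
GLDM,Small dependence low grey level emphasis,0.512551
firstorder,Interquartile range,0.498064
GLCM,Inverse difference normalised,0.456086
GLDM,Large dependence emphasis,0.450880
GLDM,Dependence variance,0.445137
GLSZM,Low grey level zone emphasis,0.445137
firstorder,Mean absolute deviation,0.414534
GLCM,Autocorrelation,0.407415
GLDM,Dependence non-uniformity normalised,0.403944
firstorder,Mean,0.389392
GLRLM,Run variance,0.375333
GLRLM,Grey level non-uniformity normalised,0.324190
GLCM,Maximum probability,0.307686
NGTDM,Strength,0.272504
GLCM,Cluster tendency,0.267111
GLCM,Inverse difference moment normalised,0.264157
GLDM,Dependence entropy,0.261878
GLRLM,Short run low grey level emphasis,0.227646
firstorder,Minimum,0.212067
GLSZM,Large area high grey level emphasis,0.202291
firstorder,Root mean squared,0.186989
GLSZM,Large area emphasis,0.178996
GLDM,Grey level variance,0.170028
GLCM,Joint average,0.160908
GLCM,Sum average,0.160908
firstorder,Uniformity,0.133892
GLDM,Small dependence high grey level emphasis,0.124894
GLSZM,Zone variance,0.119210
firstorder,Variance,0.108119
GLCM,Sum squares,0.108119
GLSZM,High grey level zone emphasis,0.105973
GLDM,Large dependence low grey level emphasis,0.082337
GLSZM,Size zone non-uniformity normalised,0.074667
GLSZM,Small area emphasis,0.073186
GLSZM,Large area low grey level emphasis,0.069577
GLRLM,Grey level variance,0.066007
GLCM,Informational measure of correlation 2,0.052283
GLRLM,Low grey level run emphasis,0.045409
GLSZM,Small area high grey level emphasis,0.044462
GLCM,Cluster prominence,0.022046
GLSZM,Grey level variance,0.021275
NGTDM,Contrast,0.020502
firstorder,10th percentile,0.015568
GLDM,Low grey level emphasis,0.014150
GLCM,Difference entropy,0.011605
GLSZM,Zone entropy,0.010051
GLRLM,Long run low grey level emphasis,0.008825
GLCM,Informational measure of correlation 1,0.006491
GLCM,Difference average,0.005938
GLCM,Maximal correlation coefficient,0.005586
GLDM,Large dependence high grey level emphasis,0.003520
firstorder,Maximum,0.002755
GLCM,Cluster shade,0.002638
firstorder,Range,0.001136
firstorder,Median,0.000355
GLCM,Contrast,0.000251
GLDM,Dependence non-uniformity,0.000230
GLSZM,Size zone non-uniformity,7.60E-05
NGTDM,Busyness,6.60E-05
GLCM,Correlation,2.40E-05
GLSZM,Grey level non-uniformity,1.40E-05
NGTDM,Complexity,1.40E-05
GLCM,Difference variance,5.00E-06
NGTDM,Coarseness,0.000000
firstorder,Skewness,0.000000
firstorder,Energy,0.000000
firstorder,Total energy,0.000000
firstorder,Kurtosis,0.000000
GLRLM,Run length non-uniformity,0.000000
GLDM,Grey level non-uniformity,0.000000
GLRLM,Grey level non-uniformity,0.000000
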
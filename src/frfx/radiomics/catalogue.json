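{
 "version": "1.0",
 "bin_width_default": 25.0,
 "aggregation": "mean over 13 symmetric 3-D directions, distance 1",
 "families": [
  {
   "name": "first_order",
   "count": 19,
   "features": [
    "firstorder_Energy",
    "firstorder_TotalEnergy",
    "firstorder_Entropy",
    "firstorder_Minimum",
    "firstorder_10Percentile",
    "firstorder_90Percentile",
    "firstorder_Maximum",
    "firstorder_Mean",
    "firstorder_Median",
    "firstorder_InterquartileRange",
    "firstorder_Range",
    "firstorder_MeanAbsoluteDeviation",
    "firstorder_RobustMeanAbsoluteDeviation",
    "firstorder_RootMeanSquared",
    "firstorder_StandardDeviation",
    "firstorder_Variance",
    "firstorder_Skewness",
    "firstorder_Kurtosis",
    "firstorder_Uniformity"
   ]
  },
  {
   "name": "shape",
   "count": 16,
   "features": [
    "shape_MeshVolume",
    "shape_VoxelVolume",
    "shape_SurfaceArea",
    "shape_SurfaceVolumeRatio",
    "shape_Sphericity",
    "shape_Compactness1",
    "shape_Compactness2",
    "shape_Maximum3DDiameter",
    "shape_Maximum2DDiameterSlice",
    "shape_Maximum2DDiameterColumn",
    "shape_Maximum2DDiameterRow",
    "shape_MajorAxisLength",
    "shape_MinorAxisLength",
    "shape_LeastAxisLength",
    "shape_Elongation",
    "shape_Flatness"
   ]
  },
  {
   "name": "glcm",
   "count": 22,
   "features": [
    "glcm_Autocorrelation",
    "glcm_ClusterProminence",
    "glcm_ClusterShade",
    "glcm_ClusterTendency",
    "glcm_Contrast",
    "glcm_Correlation",
    "glcm_DifferenceAverage",
    "glcm_DifferenceEntropy",
    "glcm_DifferenceVariance",
    "glcm_Id",
    "glcm_Idm",
    "glcm_Idmn",
    "glcm_Idn",
    "glcm_Imc1",
    "glcm_Imc2",
    "glcm_InverseVariance",
    "glcm_JointAverage",
    "glcm_JointEnergy",
    "glcm_JointEntropy",
    "glcm_MaximumProbability",
    "glcm_SumEntropy",
    "glcm_SumSquares"
   ]
  },
  {
   "name": "glrlm",
   "count": 16,
   "features": [
    "glrlm_ShortRunEmphasis",
    "glrlm_LongRunEmphasis",
    "glrlm_GrayLevelNonUniformity",
    "glrlm_GrayLevelNonUniformityNormalized",
    "glrlm_RunLengthNonUniformity",
    "glrlm_RunLengthNonUniformityNormalized",
    "glrlm_RunPercentage",
    "glrlm_GrayLevelVariance",
    "glrlm_RunVariance",
    "glrlm_RunEntropy",
    "glrlm_LowGrayLevelRunEmphasis",
    "glrlm_HighGrayLevelRunEmphasis",
    "glrlm_ShortRunLowGrayLevelEmphasis",
    "glrlm_ShortRunHighGrayLevelEmphasis",
    "glrlm_LongRunLowGrayLevelEmphasis",
    "glrlm_LongRunHighGrayLevelEmphasis"
   ]
  },
  {
   "name": "glszm",
   "count": 16,
   "features": [
    "glszm_SmallAreaEmphasis",
    "glszm_LargeAreaEmphasis",
    "glszm_GrayLevelNonUniformity",
    "glszm_GrayLevelNonUniformityNormalized",
    "glszm_SizeZoneNonUniformity",
    "glszm_SizeZoneNonUniformityNormalized",
    "glszm_ZonePercentage",
    "glszm_GrayLevelVariance",
    "glszm_ZoneVariance",
    "glszm_ZoneEntropy",
    "glszm_LowGrayLevelZoneEmphasis",
    "glszm_HighGrayLevelZoneEmphasis",
    "glszm_SmallAreaLowGrayLevelEmphasis",
    "glszm_SmallAreaHighGrayLevelEmphasis",
    "glszm_LargeAreaLowGrayLevelEmphasis",
    "glszm_LargeAreaHighGrayLevelEmphasis"
   ]
  },
  {
   "name": "gldm",
   "count": 12,
   "features": [
    "gldm_SmallDependenceEmphasis",
    "gldm_LargeDependenceEmphasis",
    "gldm_GrayLevelNonUniformity",
    "gldm_DependenceNonUniformity",
    "gldm_DependenceNonUniformityNormalized",
    "gldm_GrayLevelVariance",
    "gldm_DependenceVariance",
    "gldm_DependenceEntropy",
    "gldm_LowGrayLevelEmphasis",
    "gldm_HighGrayLevelEmphasis",
    "gldm_SmallDependenceLowGrayLevelEmphasis",
    "gldm_LargeDependenceHighGrayLevelEmphasis"
   ]
  },
  {
   "name": "ngtdm",
   "count": 5,
   "features": [
    "ngtdm_Coarseness",
    "ngtdm_Contrast",
    "ngtdm_Busyness",
    "ngtdm_Complexity",
    "ngtdm_Strength"
   ]
  }
 ]
}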
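<annotation>
  <folder>images</folder>
  <filename>phantom_0000.png</filename>
  <size>
    <width>360</width>
    <height>360</height>
    <depth>1</depth>
  </size>
  <object>
    <name>N</name>
    <pose>Unspecified</pose>
    <truncated>0</truncated>
    <difficult>0</difficult>
    <bndbox>
      <xmin>23</xmin>
      <ymin>20</ymin>
      <xmax>58</xmax>
      <ymax>61</ymax>
    </bndbox>
  </object>
  <object>
    <name>E</name>
    <pose>Unspecified</pose>
    <truncated>0</truncated>
    <difficult>0</difficult>
    <bndbox>
      <xmin>91</xmin>
      <ymin>26</ymin>
      <xmax>136</xmax>
      <ymax>55</ymax>
    </bndbox>
  </object>
  <object>
    <name>E</name>
    <pose>Unspecified</pose>
    <truncated>0</truncated>
    <difficult>0</difficult>
    <bndbox>
      <xmin>169</xmin>
      <ymin>23</ymin>
      <xmax>204</xmax>
      <ymax>58</ymax>
    </bndbox>
  </object>
  <object>
    <name>N</name>
    <pose>Unspecified</pose>
    <truncated>0</truncated>
    <difficult>0</difficult>
    <bndbox>
      <xmin>239</xmin>
      <ymin>26</ymin>
      <xmax>280</xmax>
      <ymax>55</ymax>
    </bndbox>
  </object>
  <object>
    <name>M</name>
    <pose>Unspecified</pose>
    <truncated>0</truncated>
    <difficult>0</difficult>
    <bndbox>
      <xmin>24</xmin>
      <ymin>92</ymin>
      <xmax>58</xmax>
      <ymax>136</ymax>
    </bndbox>
  </object>
  <object>
    <name>M</name>
    <pose>Unspecified</pose>
    <truncated>0</truncated>
    <difficult>0</difficult>
    <bndbox>
      <xmin>93</xmin>
      <ymin>94</ymin>
      <xmax>135</xmax>
      <ymax>134</ymax>
    </bndbox>
  </object>
</annotation>
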